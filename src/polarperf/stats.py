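"""Pixel-wise t-maps and maxT permutation thresholds with strong FWER control.

Two designs are supported: pooled-variance two-sample t-tests (group label
reshuffling under permutation) and paired t-tests on per-subject difference
maps (independent per-subject sign flips).  The observed maps are thresholded
at the order statistic ``ceil((1 - alpha) * M)`` of the collection of maximal
absolute t-values, where the collection comprises the permutation maxima plus
the observed maximum (M = B + 1 values); this convention guarantees validity
of the permutation test.  When the paired design can enumerate all ``2**n``
sign flips within the permutation budget, the exact test is used instead of
random sampling.

Zero-variance pixels get t = 0 and can never be declared significant, so
degenerate pixels do not poison the max statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Cohort
from .errors import InvalidArgumentError
from .geometry import Geometry

__all__ = [
    "ComparisonConfig",
    "ComparisonResult",
    "t_map_two_sample",
    "t_map_paired",
    "maxt_threshold",
    "compare",
]

_VAR_EPS = 1e-300  # variances at or below this count as exactly zero


@dataclass(frozen=True)
class ComparisonConfig:
    alpha: float = 0.001
    n_permutations: int = 500
    design: str = "two_sample"
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise InvalidArgumentError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise InvalidArgumentError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )
        if self.design not in ("two_sample", "paired"):
            raise InvalidArgumentError(
                f"design must be 'two_sample' or 'paired', got {self.design!r}"
            )


@dataclass
class ComparisonResult:
    """Outcome of one pixel-wise group comparison.

    ``t_map`` is NaN outside the valid disc.  ``sig_lower`` marks pixels where
    group A is significantly lower than group B (t < -threshold), ``sig_higher``
    where it is significantly higher.
    """

    t_map: np.ndarray
    max_t_distribution: np.ndarray
    threshold: float
    sig_lower: np.ndarray
    sig_higher: np.ndarray
    design: str
    n_A: int
    n_B: int
    alpha: float
    geometry: Geometry

    @property
    def n_significant(self) -> int:
        return int(self.sig_lower.sum() + self.sig_higher.sum())


def _two_sample_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Pooled-variance two-sample t; broadcasting over leading axes."""
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = sumsq_b - n_b * mean_b**2
    pooled_var = (ss_a + ss_b) / (n_a + n_b - 2)
    pooled_var = np.maximum(pooled_var, 0.0)  # guard tiny negative round-off
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    t = np.where(se <= math.sqrt(_VAR_EPS), 0.0, t)
    return t


def _paired_t(sums, sumsq, n):
    """One-sample t on difference sums; broadcasting over leading axes."""
    mean = sums / n
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t = np.where(se <= math.sqrt(_VAR_EPS), 0.0, t)
    return t


def _stacked(cohort: Cohort) -> np.ndarray:
    for pm in cohort.maps:
        if not pm.normalized:
            raise InvalidArgumentError(
                f"map {pm.meta.subject_id}/{pm.meta.correction} is not normalized"
            )
    return cohort.stacked()


def _check_geometry(cohort_a: Cohort, cohort_b: Cohort) -> Geometry:
    if not cohort_a.geometry.same_as(cohort_b.geometry):
        raise InvalidArgumentError("cohorts have mismatched geometries")
    return cohort_a.geometry


def _full_grid(values: np.ndarray, geometry: Geometry) -> np.ndarray:
    grid = np.full(geometry.valid_mask.shape, np.nan)
    grid[geometry.valid_mask] = values
    return grid


def t_map_two_sample(cohort_a: Cohort, cohort_b: Cohort) -> np.ndarray:
    """Pooled-variance two-sample t statistic per valid pixel (A minus B).

    Returns a full grid with NaN outside the valid disc.  Pixels with zero
    pooled variance get t = 0.
    """
    geometry = _check_geometry(cohort_a, cohort_b)
    x_a, x_b = _stacked(cohort_a), _stacked(cohort_b)
    if x_a.shape[0] < 2 or x_b.shape[0] < 2:
        raise InvalidArgumentError("both groups need at least 2 maps")
    t = _two_sample_t(
        x_a.sum(axis=0), (x_a**2).sum(axis=0), x_a.shape[0],
        x_b.sum(axis=0), (x_b**2).sum(axis=0), x_b.shape[0],
    )
    return _full_grid(t, geometry)


def paired_differences(cohort_nc: Cohort, cohort_ac: Cohort) -> np.ndarray:
    """(n_subjects, n_valid) matrix of per-subject A-minus-B differences.

    Subjects are aligned by id (sorted); raises PairingError on mismatch.
    """
    _check_geometry(cohort_nc, cohort_ac)
    maps_a, maps_b = cohort_nc.paired_with(cohort_ac)
    for pm in [*maps_a, *maps_b]:
        if not pm.normalized:
            raise InvalidArgumentError(
                f"map {pm.meta.subject_id}/{pm.meta.correction} is not normalized"
            )
    a = np.stack([pm.valid_values() for pm in maps_a])
    b = np.stack([pm.valid_values() for pm in maps_b])
    return a - b


def t_map_paired(cohort_a: Cohort, cohort_b: Cohort) -> np.ndarray:
    """Paired t statistic per valid pixel on A-minus-B subject differences."""
    geometry = _check_geometry(cohort_a, cohort_b)
    d = paired_differences(cohort_a, cohort_b)
    if d.shape[0] < 2:
        raise InvalidArgumentError("paired design needs at least 2 subjects")
    t = _paired_t(d.sum(axis=0), (d**2).sum(axis=0), d.shape[0])
    return _full_grid(t, geometry)


def _threshold_from_collection(collection: np.ndarray, alpha: float) -> float:
    m = collection.size
    k = math.ceil((1.0 - alpha) * m)
    k = min(max(k, 1), m)
    return float(np.sort(collection)[k - 1])


def _resolution_warning(config: ComparisonConfig):
    if config.n_permutations < 1.0 / config.alpha - 1.0:
        warnings.warn(
            f"alpha={config.alpha} is below the resolution of B="
            f"{config.n_permutations} permutations (needs B >= 1/alpha - 1); "
            "the threshold equals the maximum of the null collection and no "
            "pixel can be declared significant",
            stacklevel=3,
        )


def _maxt_two_sample(x_a: np.ndarray, x_b: np.ndarray, config: ComparisonConfig):
    n_a, n_b = x_a.shape[0], x_b.shape[0]
    if n_a < 2 or n_b < 2:
        raise InvalidArgumentError("both groups need at least 2 maps for permutation")
    x = np.vstack([x_a, x_b])
    n = n_a + n_b
    total_sum = x.sum(axis=0)
    total_sumsq = (x**2).sum(axis=0)

    rng = np.random.default_rng(config.seed)
    b = config.n_permutations
    # B x n one-hot matrix of group-A membership; label reshuffle preserving sizes
    assign = np.zeros((b, n))
    for i in range(b):
        assign[i, rng.permutation(n)[:n_a]] = 1.0
    sum_a = assign @ x
    sumsq_a = assign @ (x**2)
    t_perm = _two_sample_t(
        sum_a, sumsq_a, n_a, total_sum - sum_a, total_sumsq - sumsq_a, n_b
    )
    max_perm = np.abs(t_perm).max(axis=1)

    t_obs = _two_sample_t(
        x_a.sum(axis=0), (x_a**2).sum(axis=0), n_a,
        x_b.sum(axis=0), (x_b**2).sum(axis=0), n_b,
    )
    collection = np.append(max_perm, np.abs(t_obs).max())
    return t_obs, collection


def _maxt_paired(d: np.ndarray, config: ComparisonConfig):
    n = d.shape[0]
    if n < 2:
        raise InvalidArgumentError("paired design needs at least 2 subjects for permutation")
    sumsq = (d**2).sum(axis=0)  # invariant under sign flips
    t_obs = _paired_t(d.sum(axis=0), sumsq, n)

    exhaustive = n <= 62 and 2**n <= config.n_permutations
    if exhaustive:
        # all 2**n sign patterns; the identity pattern supplies the observed max
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 2.0 * bits - 1.0
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    sums = signs @ d
    t_perm = _paired_t(sums, sumsq, n)
    max_perm = np.abs(t_perm).max(axis=1)
    if exhaustive:
        collection = max_perm
    else:
        collection = np.append(max_perm, np.abs(t_obs).max())
    return t_obs, collection


def maxt_threshold(data, config: ComparisonConfig):
    """Permutation max-|t| threshold for the configured design.

    Parameters
    ----------
    data:
        For ``design='two_sample'``: a tuple ``(X_A, X_B)`` of
        (n_maps, n_pixels) matrices.  For ``design='paired'``: a
        (n_subjects, n_pixels) matrix of per-subject differences.
    config:
        Permutation count, alpha, design and seed.

    Returns
    -------
    (threshold, max_t_distribution):
        ``max_t_distribution`` is the full null collection (permutation maxima
        plus the observed maximum, or the exhaustive enumeration for small
        paired designs); ``threshold`` is its ``ceil((1 - alpha) * M)``-th
        order statistic.
    """
    _resolution_warning(config)
    if config.design == "two_sample":
        x_a, x_b = data
        _, collection = _maxt_two_sample(np.asarray(x_a, float), np.asarray(x_b, float), config)
    else:
        _, collection = _maxt_paired(np.asarray(data, float), config)
    return _threshold_from_collection(collection, config.alpha), collection


def compare(
    cohort_a: Cohort, cohort_b: Cohort, config: ComparisonConfig
) -> ComparisonResult:
    """Full pixel-wise comparison of two cohorts with maxT FWER control.

    Composes the design-appropriate t-map with the permutation threshold and
    derives signed significance masks (strict ``|t| > threshold``).
    """
    geometry = _check_geometry(cohort_a, cohort_b)
    _resolution_warning(config)
    if config.design == "two_sample":
        x_a, x_b = _stacked(cohort_a), _stacked(cohort_b)
        t_valid, collection = _maxt_two_sample(x_a, x_b, config)
        n_a, n_b = x_a.shape[0], x_b.shape[0]
    else:
        d = paired_differences(cohort_a, cohort_b)
        t_valid, collection = _maxt_paired(d, config)
        n_a = n_b = d.shape[0]
    threshold = _threshold_from_collection(collection, config.alpha)
    t_map = _full_grid(t_valid, geometry)
    with np.errstate(invalid="ignore"):
        sig_lower = np.nan_to_num(t_map, nan=0.0) < -threshold
        sig_higher = np.nan_to_num(t_map, nan=0.0) > threshold
    sig_lower &= geometry.valid_mask
    sig_higher &= geometry.valid_mask
    return ComparisonResult(
        t_map=t_map,
        max_t_distribution=collection,
        threshold=threshold,
        sig_lower=sig_lower,
        sig_higher=sig_higher,
        design=config.design,
        n_A=n_a,
        n_B=n_b,
        alpha=config.alpha,
        geometry=geometry,
    )
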