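"""Count normalization: scale each map by the median of its brightest pixels.

Each map is scaled so that the median count within the 10% highest-count
valid pixels equals a common reference value (100 by default), which places
all maps on a comparable scale where segmental differences live naturally in
-100..100 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Cohort, PolarMap
from .errors import InvalidArgumentError, NormalizationError

__all__ = ["NormalizationConfig", "top_set_indices", "normalize_map", "normalize_cohort"]


@dataclass(frozen=True)
class NormalizationConfig:
    top_fraction: float = 0.10
    reference_value: float = 100.0

    def __post_init__(self):
        if not (0.0 < self.top_fraction <= 1.0):
            raise InvalidArgumentError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.reference_value <= 0:
            raise InvalidArgumentError(
                f"reference_value must be positive, got {self.reference_value}"
            )


def top_set_indices(values: np.ndarray, top_fraction: float) -> np.ndarray:
    """Indices (into ``values``) of the ``ceil(top_fraction * n)`` largest entries.

    Ties at the selection boundary are resolved by taking the lowest index
    first, so the selection is deterministic.
    """
    values = np.asarray(values, dtype=float)
    k = math.ceil(top_fraction * values.size)
    # stable sort on descending value keeps lowest original index first on ties
    order = np.argsort(-values, kind="stable")
    return order[:k]


def scale_factor(pmap: PolarMap, config: NormalizationConfig = NormalizationConfig()) -> float:
    """Multiplicative factor that normalizes ``pmap`` (reference / top-set median)."""
    values = pmap.valid_values()
    if int(np.sum(values > 0)) < 10:
        raise NormalizationError(
            f"map {pmap.meta.subject_id}/{pmap.meta.correction}: fewer than 10 valid "
            "pixels with positive counts; normalization scale undefined"
        )
    top = values[top_set_indices(values, config.top_fraction)]
    med = float(np.median(top))
    if med <= 0:
        raise NormalizationError(
            f"map {pmap.meta.subject_id}/{pmap.meta.correction}: top-set median is "
            "non-positive; normalization scale undefined"
        )
    return config.reference_value / med


def normalize_map(
    pmap: PolarMap, config: NormalizationConfig = NormalizationConfig()
) -> PolarMap:
    """Return a copy of ``pmap`` scaled so its top-set median equals the reference.

    The median is taken over the ``ceil(top_fraction * n_valid)`` valid pixels
    of highest count (even-sized sets use the mean of the two central order
    statistics).  Idempotent and invariant to positive rescaling of the input.
    """
    factor = scale_factor(pmap, config)
    return pmap.with_counts(pmap.counts * factor, normalized=True)


def normalize_cohort(
    cohort: Cohort, config: NormalizationConfig = NormalizationConfig()
) -> Cohort:
    """Normalize every map in the cohort independently (NC and AC alike)."""
    if not cohort.maps:
        raise InvalidArgumentError("cannot normalize an empty cohort")
    out = []
    for pm in cohort.maps:
        try:
            out.append(normalize_map(pm, config))
        except NormalizationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context wrapper
            raise NormalizationError(
                f"normalization failed for subject {pm.meta.subject_id} "
                f"({pm.meta.correction}): {exc}"
            ) from exc
    return Cohort(maps=out, geometry=cohort.geometry)
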