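"""Synthetic paired NC/AC polar-map cohorts with attenuation-like structure.

The generator reproduces, on demand, the qualitative structure of a clinical
normal-stress cohort: non-corrected (NC) maps carry smooth regional count
deficits that depend on gender (inferior wall in men; anterior and lateral
walls in women) and are amplified by obesity, while attenuation-corrected
(AC) maps retain only a small residual of those deficits.  Per-subject
intensity variation is a multiplicative log-normal scale shared between a
subject's NC and AC maps, and pixel noise is spatially correlated via
Gaussian smoothing.

``calibrate_to_segment_targets`` tunes deficit amplitudes (and the AC
residual) by deterministic root-finding against the noise-free forward model
run through the actual normalization and segmental stages, so that the
population-level segmental differences match requested values on the
-100..100 normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .core import BMI_CLASSES, Cohort, PolarMap, SubjectMeta
from .errors import CalibrationError, InvalidArgumentError
from .geometry import Geometry, SEGMENT_NAMES, make_geometry, make_segments, radial_angular
from .normalization import NormalizationConfig, normalize_map

__all__ = [
    "GeneratorConfig",
    "STUDY_STRATA",
    "COMPARISON_KEYS",
    "deficit_field",
    "generate_subject",
    "generate_cohort",
    "calibrate_to_segment_targets",
]

#: Stratum sizes of the source cohort (gender, bmi_class) -> n subjects.
STUDY_STRATA = {
    ("male", "normal"): 102,
    ("male", "obese"): 24,
    ("female", "normal"): 165,
    ("female", "obese"): 40,
}

#: Comparison keys accepted by the calibrator.  Direction conventions:
#: gender comparisons are men minus women; correction comparisons NC minus AC.
COMPARISON_KEYS = (
    "nc_men_vs_women",
    "ac_men_vs_women",
    "men_nc_vs_ac",
    "women_nc_vs_ac",
)

# Deficit bump placement in (angle, radius) space: segment-centered smooth
# Gaussian windows.  Angles per the display convention (inferior 270, anterior
# 90, lateral 0); radial center mid-wall.
_BUMP_ANGLE = {"male_inferior": 270.0, "female_anterior": 90.0, "female_lateral": 0.0}
_BUMP_ANGLE_SIGMA = 25.0  # degrees; keeps the bump essentially within one quadrant
_BUMP_RADIUS_CENTER = 0.60
_BUMP_RADIUS_SIGMA = 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Fractional deficits are peak amplitudes of Gaussian windows in
    (angle, radius) space; ``ac_residual`` is the fraction of the NC deficit
    remaining after attenuation correction.
    """

    base_level: float = 100.0
    base_pattern: Mapping[str, float] | None = None  # optional {"radial": a, "angular": b}
    nc_effect_male_inferior: float = 0.14
    nc_effect_female_anterior: float = 0.06
    nc_effect_female_lateral: float = 0.04
    obesity_multiplier: float = 1.5
    ac_residual: float = 0.1
    subject_sd: float = 0.10
    pixel_noise_sd: float = 6.0
    noise_smooth_sigma: float = 1.5
    seed: int | None = None

    def __post_init__(self):
        fractions = {
            "nc_effect_male_inferior": self.nc_effect_male_inferior,
            "nc_effect_female_anterior": self.nc_effect_female_anterior,
            "nc_effect_female_lateral": self.nc_effect_female_lateral,
            "ac_residual": self.ac_residual,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise InvalidArgumentError(f"{name} must be in [0, 1], got {value}")
        if self.base_level <= 0:
            raise InvalidArgumentError(f"base_level must be positive, got {self.base_level}")
        if self.subject_sd < 0 or self.pixel_noise_sd < 0 or self.noise_smooth_sigma < 0:
            raise InvalidArgumentError("SDs and smoothing sigma must be non-negative")
        if self.obesity_multiplier < 0:
            raise InvalidArgumentError("obesity_multiplier must be non-negative")
        if self.base_pattern is not None:
            unknown = set(self.base_pattern) - {"radial", "angular"}
            if unknown:
                raise InvalidArgumentError(f"unknown base_pattern keys: {sorted(unknown)}")


def _angular_gaussian(angle_deg: np.ndarray, center_deg: float, sigma_deg: float) -> np.ndarray:
    delta = (angle_deg - center_deg + 180.0) % 360.0 - 180.0
    return np.exp(-0.5 * (delta / sigma_deg) ** 2)


def _bump(angle_deg: np.ndarray, radius_norm: np.ndarray, center_deg: float) -> np.ndarray:
    ang = _angular_gaussian(angle_deg, center_deg, _BUMP_ANGLE_SIGMA)
    rad = np.exp(-0.5 * ((radius_norm - _BUMP_RADIUS_CENTER) / _BUMP_RADIUS_SIGMA) ** 2)
    return ang * rad


def base_pattern_map(config: GeneratorConfig, geometry: Geometry) -> np.ndarray:
    """Noise-free base count pattern (before deficits), full grid."""
    radius_norm, angle_deg = radial_angular(geometry)
    pattern = np.full(radius_norm.shape, float(config.base_level))
    if config.base_pattern:
        radial = float(config.base_pattern.get("radial", 0.0))
        angular = float(config.base_pattern.get("angular", 0.0))
        pattern = pattern * (1.0 - radial * (radius_norm - 0.5) ** 2)
        pattern = pattern * (1.0 + angular * np.cos(np.radians(angle_deg)))
    return pattern


def deficit_field(
    config: GeneratorConfig, geometry: Geometry, gender: str, bmi_class: str
) -> np.ndarray:
    """Fractional NC count deficit per pixel (0..1) for one stratum."""
    radius_norm, angle_deg = radial_angular(geometry)
    total = np.zeros(radius_norm.shape)
    if gender == "male":
        total += config.nc_effect_male_inferior * _bump(
            angle_deg, radius_norm, _BUMP_ANGLE["male_inferior"]
        )
    else:
        total += config.nc_effect_female_anterior * _bump(
            angle_deg, radius_norm, _BUMP_ANGLE["female_anterior"]
        )
        total += config.nc_effect_female_lateral * _bump(
            angle_deg, radius_norm, _BUMP_ANGLE["female_lateral"]
        )
    if bmi_class == "obese":
        total = total * config.obesity_multiplier
    return np.clip(total, 0.0, 1.0)


def noiseless_map(
    config: GeneratorConfig,
    geometry: Geometry,
    gender: str,
    bmi_class: str,
    correction: str,
) -> np.ndarray:
    """Population-mean (noise-free, unit subject scale) count grid for a stratum."""
    deficit = deficit_field(config, geometry, gender, bmi_class)
    if correction == "AC":
        deficit = config.ac_residual * deficit
    return base_pattern_map(config, geometry) * (1.0 - deficit)


def _smoothed_noise(
    rng: np.random.Generator, config: GeneratorConfig, shape: tuple[int, int]
) -> np.ndarray:
    noise = rng.normal(0.0, config.pixel_noise_sd, size=shape) if config.pixel_noise_sd > 0 else np.zeros(shape)
    if config.noise_smooth_sigma > 0 and config.pixel_noise_sd > 0:
        noise = gaussian_filter(noise, sigma=config.noise_smooth_sigma)
    return noise


def generate_subject(
    config: GeneratorConfig,
    subject_id: str,
    gender: str,
    bmi_class: str,
    rng: np.random.Generator,
    geometry: Geometry | None = None,
) -> tuple[PolarMap, PolarMap]:
    """Generate one subject's paired (NC, AC) maps.

    Both maps share one multiplicative subject scale; pixel noise is drawn
    independently per map and smoothed.  Counts are clipped at zero.  Draws
    are consumed in a fixed order (scale, NC noise, AC noise) so generation is
    reproducible bit-for-bit under a fixed RNG state.
    """
    geometry = geometry if geometry is not None else make_geometry()
    scale = float(np.exp(rng.normal(0.0, config.subject_sd))) if config.subject_sd > 0 else 1.0
    maps = []
    for correction in ("NC", "AC"):
        counts = noiseless_map(config, geometry, gender, bmi_class, correction) * scale
        counts = counts + _smoothed_noise(rng, config, counts.shape)
        counts = np.clip(counts, 0.0, None)
        counts[~geometry.valid_mask] = np.nan
        maps.append(
            PolarMap(
                counts=counts,
                meta=SubjectMeta(
                    subject_id=subject_id,
                    gender=gender,
                    bmi_class=bmi_class,
                    correction=correction,
                ),
                geometry=geometry,
            )
        )
    return maps[0], maps[1]


def generate_cohort(
    config: GeneratorConfig,
    n_male_normal: int = 102,
    n_male_obese: int = 24,
    n_female_normal: int = 165,
    n_female_obese: int = 40,
    seed: int | None = None,
    geometry: Geometry | None = None,
) -> Cohort:
    """Generate a paired NC/AC cohort with the given stratum sizes.

    Default sizes mirror the source study's strata (126 men, 205 women).
    ``seed`` overrides ``config.seed``; with a fixed seed the cohort is
    bit-identical across calls.
    """
    ns = {
        ("male", "normal"): n_male_normal,
        ("male", "obese"): n_male_obese,
        ("female", "normal"): n_female_normal,
        ("female", "obese"): n_female_obese,
    }
    if any(n < 0 for n in ns.values()):
        raise InvalidArgumentError("stratum sizes must be non-negative")
    if sum(ns.values()) == 0:
        raise InvalidArgumentError("at least one stratum size must be positive")
    geometry = geometry if geometry is not None else make_geometry()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    maps: list[PolarMap] = []
    counter = 0
    for (gender, bmi_class), n in ns.items():
        for _ in range(n):
            counter += 1
            subject_id = f"S{counter:04d}-{gender[0].upper()}{bmi_class[0].upper()}"
            nc, ac = generate_subject(config, subject_id, gender, bmi_class, rng, geometry)
            maps.extend([nc, ac])
    return Cohort(maps=maps, geometry=geometry)


# ---------------------------------------------------------------------------
# Calibration against segmental targets
# ---------------------------------------------------------------------------

# Which config field each (comparison, segment) target tunes.
_TARGET_PARAM = {
    ("nc_men_vs_women", "inferior"): "nc_effect_male_inferior",
    ("men_nc_vs_ac", "inferior"): "nc_effect_male_inferior",
    ("nc_men_vs_women", "anterior"): "nc_effect_female_anterior",
    ("nc_men_vs_women", "lateral"): "nc_effect_female_lateral",
    ("ac_men_vs_women", "inferior"): "ac_residual",
}

_COMPARISON_GROUPS = {
    # (group A, group B) as (gender, correction)
    "nc_men_vs_women": (("male", "NC"), ("female", "NC")),
    "ac_men_vs_women": (("male", "AC"), ("female", "AC")),
    "men_nc_vs_ac": (("male", "NC"), ("male", "AC")),
    "women_nc_vs_ac": (("female", "NC"), ("female", "AC")),
}


def _normalized_group_mean(
    config: GeneratorConfig,
    geometry: Geometry,
    gender: str,
    correction: str,
    strata: Mapping[tuple[str, str], int],
) -> np.ndarray:
    """Noise-free normalized population mean map for one (gender, correction).

    Mixes BMI strata with the cohort's proportions; every subject in a
    stratum is identical in the noise-free limit (the subject scale cancels
    under per-map normalization).
    """
    norm_cfg = NormalizationConfig()
    weights = {b: strata.get((gender, b), 0) for b in BMI_CLASSES}
    total = sum(weights.values())
    if total == 0:
        raise InvalidArgumentError(f"no subjects of gender {gender!r} in strata")
    acc = np.zeros(geometry.valid_mask.shape)
    for bmi_class, w in weights.items():
        if w == 0:
            continue
        counts = noiseless_map(config, geometry, gender, bmi_class, correction)
        counts = counts.copy()
        counts[~geometry.valid_mask] = np.nan
        pm = PolarMap(
            counts=counts,
            meta=SubjectMeta(f"_cal_{gender}_{bmi_class}", gender, bmi_class, correction),
            geometry=geometry,
        )
        acc += (w / total) * normalize_map(pm, norm_cfg).counts
    return acc


def population_segment_diff(
    config: GeneratorConfig,
    comparison: str,
    segment: str,
    strata: Mapping[tuple[str, str], int] = STUDY_STRATA,
    geometry: Geometry | None = None,
) -> float:
    """Noise-free (infinite-n) segmental mean difference for one comparison.

    Runs the actual normalization and segment geometry, so calibration and
    the Monte Carlo pipeline agree by construction.
    """
    if comparison not in _COMPARISON_GROUPS:
        raise InvalidArgumentError(
            f"unknown comparison {comparison!r}; expected one of {COMPARISON_KEYS}"
        )
    if segment not in SEGMENT_NAMES:
        raise InvalidArgumentError(f"unknown segment {segment!r}; expected one of {SEGMENT_NAMES}")
    geometry = geometry if geometry is not None else make_geometry()
    (gender_a, corr_a), (gender_b, corr_b) = _COMPARISON_GROUPS[comparison]
    mean_a = _normalized_group_mean(config, geometry, gender_a, corr_a, strata)
    mean_b = _normalized_group_mean(config, geometry, gender_b, corr_b, strata)
    mask = getattr(make_segments(geometry), segment)
    return float(np.mean((mean_a - mean_b)[mask]))


def calibrate_to_segment_targets(
    targets: Mapping[tuple[str, str], float],
    config: GeneratorConfig,
    strata: Mapping[tuple[str, str], int] = STUDY_STRATA,
    tolerance: float = 0.5,
) -> GeneratorConfig:
    """Tune deficit parameters so noise-free segmental differences hit targets.

    Parameters
    ----------
    targets:
        Mapping of (comparison key, segment name) to the desired mean count
        difference on the -100..100 normalized scale.  Supported pairs and
        the parameter each tunes: NC men-vs-women inferior / anterior /
        lateral (the corresponding deficit amplitude), men NC-vs-AC inferior
        (the male inferior amplitude), AC men-vs-women inferior (the AC
        residual).
    config:
        Starting configuration; returned updated.
    strata:
        Cohort composition used by the noise-free forward model (defaults to
        the source study's stratum sizes).

    Raises
    ------
    CalibrationError
        If a target is outside [-100, 100], maps to no tunable parameter,
        conflicts with another target for the same parameter, or cannot be
        reached within the parameter's [0, 1] bounds.
    """
    for (comparison, segment), value in targets.items():
        if not (-100.0 <= value <= 100.0):
            raise CalibrationError(
                f"target {value} for {comparison}/{segment} outside [-100, 100]",
                segment=segment,
            )
        if (comparison, segment) not in _TARGET_PARAM:
            raise CalibrationError(
                f"no tunable parameter for target {comparison}/{segment}", segment=segment
            )

    params_used: dict[str, tuple[str, str]] = {}
    for key in targets:
        param = _TARGET_PARAM[key]
        if param in params_used:
            raise CalibrationError(
                f"targets {params_used[param]} and {key} both tune {param}",
                segment=key[1],
            )
        params_used[param] = key

    geometry = make_geometry()

    def solve(cfg: GeneratorConfig, param: str, key: tuple[str, str]) -> GeneratorConfig:
        """One coordinate update: root of the forward model in ``param``.

        If the target has no root within the parameter's [0, 1] bounds the
        parameter is clamped to the better boundary; the final tolerance
        check after the fixed-point iteration decides whether that is fatal.
        """
        comparison, segment = key
        target = targets[key]

        def objective(x: float) -> float:
            return (
                population_segment_diff(
                    replace(cfg, **{param: x}), comparison, segment, strata, geometry
                )
                - target
            )

        lo, hi = 0.0, 1.0
        f_lo, f_hi = objective(lo), objective(hi)
        if abs(f_lo) <= 1e-9:
            root = lo
        elif abs(f_hi) <= 1e-9:
            root = hi
        elif f_lo * f_hi > 0:
            root = lo if abs(f_lo) <= abs(f_hi) else hi
        else:
            root = brentq(objective, lo, hi, xtol=1e-10)
        return replace(cfg, **{param: float(root)})

    # Amplitudes first, then the AC residual (whose effect depends on them).
    # Deficit windows overlap slightly, so iterate the sequential solve to a
    # joint fixed point.
    ordered = sorted(params_used.items(), key=lambda kv: kv[0] == "ac_residual")
    out = config
    for _ in range(8):
        previous = out
        for param, key in ordered:
            out = solve(out, param, key)
        drift = max(
            abs(getattr(out, param) - getattr(previous, param)) for param, _ in ordered
        )
        if drift < 1e-9:
            break
    for param, (comparison, segment) in params_used.items():
        achieved = population_segment_diff(out, comparison, segment, strata, geometry)
        if abs(achieved - targets[(comparison, segment)]) > tolerance:
            raise CalibrationError(
                f"calibration for {comparison}/{segment} achieved {achieved:.3f}, "
                f"target {targets[(comparison, segment)]:.3f} (tolerance {tolerance}); "
                f"unreachable within [0, 1] bounds of {param}",
                segment=segment,
            )
    return out
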