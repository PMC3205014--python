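import numpy as np
import pytest

from polarperf import (
    Cohort,
    GeneratorConfig,
    PolarMap,
    SubjectMeta,
    make_geometry,
    make_segments,
)


@pytest.fixture(scope="session")
def geometry():
    return make_geometry(65)


@pytest.fixture(scope="session")
def segments(geometry):
    return make_segments(geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_map(geometry, values, subject_id="s1", gender="male", bmi="normal",
             correction="NC", normalized=False):
    """Build a PolarMap from a full grid or a scalar fill value."""
    if np.isscalar(values):
        counts = np.full(geometry.valid_mask.shape, float(values))
    else:
        counts = np.asarray(values, dtype=float).copy()
    counts[~geometry.valid_mask] = np.nan
    meta = SubjectMeta(subject_id, gender, bmi, correction)
    return PolarMap(counts=counts, meta=meta, geometry=geometry, normalized=normalized)


def random_map(geometry, rng, subject_id="s1", lo=10.0, hi=200.0, **kw):
    values = rng.uniform(lo, hi, size=geometry.valid_mask.shape)
    return make_map(geometry, values, subject_id=subject_id, **kw)


def random_cohort(geometry, rng, n=5, correction="NC", normalized=False, **kw):
    maps = [
        random_map(geometry, rng, subject_id=f"s{i}", correction=correction,
                   normalized=normalized, **kw)
        for i in range(n)
    ]
    return Cohort(maps=maps, geometry=geometry)


@pytest.fixture
def quiet_generator():
    """Noise-free generator config with no deficits."""
    return GeneratorConfig(
        nc_effect_male_inferior=0.0,
        nc_effect_female_anterior=0.0,
        nc_effect_female_lateral=0.0,
        subject_sd=0.0,
        pixel_noise_sd=0.0,
    )
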