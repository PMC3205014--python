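import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from polarperf import (
    Cohort,
    ComparisonConfig,
    InvalidArgumentError,
    PairingError,
    compare,
    make_geometry,
    maxt_threshold,
    t_map_paired,
    t_map_two_sample,
)

from conftest import make_map, random_cohort


def _paired_cohorts(geometry, rng, n=5, delta=0.0):
    nc, ac = [], []
    for i in range(n):
        base = rng.uniform(50, 150, size=geometry.valid_mask.shape)
        nc.append(make_map(geometry, base + delta, subject_id=f"s{i}", correction="NC",
                           normalized=True))
        ac.append(make_map(
            geometry, base + rng.normal(0, 1, size=base.shape) ** 2,
            subject_id=f"s{i}", correction="AC", normalized=True))
    return (Cohort(maps=nc, geometry=geometry), Cohort(maps=ac, geometry=geometry))


class TestTMapTwoSample:
    def test_identical_cohorts_zero(self, geometry, rng):
        cohort = random_cohort(geometry, rng, n=3, normalized=True)
        t = t_map_two_sample(cohort, cohort)
        assert np.all(t[geometry.valid_mask] == 0.0)

    def test_pinned_hand_computed_value(self, geometry):
        # pixel values {1,2,3} vs {4,5,6}: mean diff -3, pooled SD 1,
        # SE = sqrt(2/3) -> t = -3.674 (pinned against scipy.stats.ttest_ind)
        a = Cohort(
            maps=[make_map(geometry, v, subject_id=f"a{v}", normalized=True) for v in (1, 2, 3)],
            geometry=geometry,
        )
        b = Cohort(
            maps=[make_map(geometry, v, subject_id=f"b{v}", normalized=True) for v in (4, 5, 6)],
            geometry=geometry,
        )
        t = t_map_two_sample(a, b)
        assert t[32, 32] == pytest.approx(-3.6742346141747673, abs=1e-3)

    def test_oracle_equivalence_per_pixel(self, geometry, rng):
        a = random_cohort(geometry, rng, n=5, normalized=True)
        b = random_cohort(geometry, rng, n=5, normalized=True)
        t = t_map_two_sample(a, b)[geometry.valid_mask]
        xa, xb = a.stacked(), b.stacked()
        idx = rng.choice(xa.shape[1], size=200, replace=False)
        for j in idx:
            expected = sps.ttest_ind(xa[:, j], xb[:, j]).statistic
            assert t[j] == pytest.approx(expected, abs=1e-10)

    def test_antisymmetry(self, geometry, rng):
        a = random_cohort(geometry, rng, n=4, normalized=True)
        b = random_cohort(geometry, rng, n=6, normalized=True)
        np.testing.assert_allclose(
            t_map_two_sample(a, b)[geometry.valid_mask],
            -t_map_two_sample(b, a)[geometry.valid_mask],
            atol=1e-12,
        )

    def test_zero_variance_pixel_gets_zero(self, geometry):
        a = Cohort(
            maps=[make_map(geometry, 5.0, subject_id=f"a{i}", normalized=True) for i in range(3)],
            geometry=geometry,
        )
        b = Cohort(
            maps=[make_map(geometry, 5.0, subject_id=f"b{i}", normalized=True) for i in range(3)],
            geometry=geometry,
        )
        assert np.all(t_map_two_sample(a, b)[geometry.valid_mask] == 0.0)

    def test_geometry_mismatch(self, geometry, rng):
        other = make_geometry(33)
        a = random_cohort(geometry, rng, n=3, normalized=True)
        b = random_cohort(other, rng, n=3, normalized=True)
        with pytest.raises(InvalidArgumentError):
            t_map_two_sample(a, b)

    def test_unnormalized_rejected(self, geometry, rng):
        a = random_cohort(geometry, rng, n=3, normalized=False)
        with pytest.raises(InvalidArgumentError):
            t_map_two_sample(a, a)


class TestTMapPaired:
    def test_cohort_paired_with_itself_zero(self, geometry, rng):
        cohort = random_cohort(geometry, rng, n=4, normalized=True)
        t = t_map_paired(cohort, cohort)
        assert np.all(t[geometry.valid_mask] == 0.0)

    def test_constant_difference_zero_variance_rule(self, geometry):
        nc = Cohort(
            maps=[make_map(geometry, 11.0, subject_id=f"s{i}", correction="NC", normalized=True)
                  for i in range(4)],
            geometry=geometry,
        )
        ac = Cohort(
            maps=[make_map(geometry, 10.0, subject_id=f"s{i}", correction="AC", normalized=True)
                  for i in range(4)],
            geometry=geometry,
        )
        # d = {1,1,1,1}: zero variance -> t defined as 0, never significant
        assert np.all(t_map_paired(nc, ac)[geometry.valid_mask] == 0.0)

    def test_oracle_equivalence(self, geometry, rng):
        nc, ac = _paired_cohorts(geometry, rng, n=5)
        t = t_map_paired(nc, ac)[geometry.valid_mask]
        d = nc.stacked() - ac.stacked()
        idx = rng.choice(d.shape[1], size=200, replace=False)
        for j in idx:
            expected = sps.ttest_1samp(d[:, j], 0.0).statistic
            assert t[j] == pytest.approx(expected, abs=1e-10)

    def test_unmatched_subjects(self, geometry, rng):
        nc = random_cohort(geometry, rng, n=3, correction="NC", normalized=True)
        ac = Cohort(
            maps=[make_map(geometry, 5.0, subject_id=f"other{i}", correction="AC", normalized=True)
                  for i in range(3)],
            geometry=geometry,
        )
        with pytest.raises(PairingError) as exc:
            t_map_paired(nc, ac)
        assert "other0" in str(exc.value)


class TestMaxtThreshold:
    def test_exhaustive_matches_enumeration_oracle(self, rng):
        n, p, alpha = 5, 40, 0.1
        d = rng.normal(size=(n, p))
        config = ComparisonConfig(alpha=alpha, n_permutations=32, design="paired", seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            threshold, collection = maxt_threshold(d, config)
        assert collection.size == 32
        maxima = []
        for signs in itertools.product((-1.0, 1.0), repeat=n):
            flipped = d * np.asarray(signs)[:, None]
            t = np.array([sps.ttest_1samp(flipped[:, j], 0.0).statistic for j in range(p)])
            maxima.append(np.abs(t).max())
        k = math.ceil((1 - alpha) * len(maxima))
        assert threshold == pytest.approx(sorted(maxima)[k - 1], abs=1e-10)

    def test_alpha_half_threshold_at_most_median(self, rng):
        d = rng.normal(size=(8, 30))
        config = ComparisonConfig(alpha=0.5, n_permutations=99, design="paired", seed=1)
        threshold, collection = maxt_threshold(d, config)
        assert threshold <= np.median(collection)

    def test_threshold_nonincreasing_in_alpha(self, rng):
        xa, xb = rng.normal(size=(6, 50)), rng.normal(size=(7, 50))
        thresholds = []
        for alpha in (0.01, 0.05, 0.2, 0.5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thr, _ = maxt_threshold(
                    (xa, xb),
                    ComparisonConfig(alpha=alpha, n_permutations=99, design="two_sample", seed=7),
                )
            thresholds.append(thr)
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_resolution_warning(self, rng):
        d = rng.normal(size=(20, 30))
        with pytest.warns(UserWarning, match="resolution"):
            maxt_threshold(
                d, ComparisonConfig(alpha=0.001, n_permutations=99, design="paired", seed=0)
            )

    def test_paired_n1_rejected(self):
        with pytest.raises(InvalidArgumentError):
            maxt_threshold(
                np.ones((1, 10)),
                ComparisonConfig(alpha=0.1, n_permutations=10, design="paired", seed=0),
            )

    def test_determinism(self, rng):
        xa, xb = rng.normal(size=(5, 40)), rng.normal(size=(5, 40))
        config = ComparisonConfig(alpha=0.05, n_permutations=99, design="two_sample", seed=3)
        t1 = maxt_threshold((xa, xb), config)
        t2 = maxt_threshold((xa, xb), config)
        assert t1[0] == t2[0]
        np.testing.assert_array_equal(t1[1], t2[1])

    def test_fwer_control_nondegenerate_alpha(self):
        # alpha = 0.05 with B = 199 has resolution, so rejections can occur;
        # under a complete null the family-wise error stays within binomial
        # slack of alpha. Small grids keep this fast.
        alpha, runs = 0.05, 200
        rejections = 0
        master = np.random.default_rng(2024)
        for _ in range(runs):
            xa = master.normal(size=(10, 200))
            xb = master.normal(size=(10, 200))
            config = ComparisonConfig(
                alpha=alpha, n_permutations=199, design="two_sample",
                seed=int(master.integers(2**31)),
            )
            threshold, collection = maxt_threshold((xa, xb), config)
            t_obs = collection[-1]  # observed max |t| is appended last
            rejections += t_obs > threshold
        slack = 2.5 * math.sqrt(alpha * (1 - alpha) / runs)
        assert rejections / runs <= alpha + slack


class TestCompare:
    def test_antisymmetry_paired(self, geometry, rng):
        nc, ac = _paired_cohorts(geometry, rng, n=6)
        config = ComparisonConfig(alpha=0.05, n_permutations=64, design="paired", seed=5)
        fwd = compare(nc, ac, config)
        rev = compare(ac, nc, config)
        np.testing.assert_allclose(
            fwd.t_map[geometry.valid_mask], -rev.t_map[geometry.valid_mask], atol=1e-10
        )
        assert fwd.threshold == pytest.approx(rev.threshold, abs=1e-12)
        np.testing.assert_array_equal(fwd.sig_lower, rev.sig_higher)
        np.testing.assert_array_equal(fwd.sig_higher, rev.sig_lower)

    def test_masks_disjoint_and_within_valid(self, geometry, rng):
        a = random_cohort(geometry, rng, n=5, normalized=True)
        b = random_cohort(geometry, rng, n=5, normalized=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = compare(
                a, b, ComparisonConfig(alpha=0.05, n_permutations=99,
                                       design="two_sample", seed=1)
            )
        assert not (result.sig_lower & result.sig_higher).any()
        assert not (result.sig_lower & ~geometry.valid_mask).any()
        assert not (result.sig_higher & ~geometry.valid_mask).any()
        assert result.n_A == result.n_B == 5

    def test_strong_signal_detected_with_direction(self, geometry, rng):
        a = random_cohort(geometry, rng, n=8, normalized=True, lo=100, hi=110)
        b_maps = [
            make_map(
                geometry,
                rng.uniform(100, 110, size=geometry.valid_mask.shape) + 50.0,
                subject_id=f"b{i}", normalized=True,
            )
            for i in range(8)
        ]
        b = Cohort(maps=b_maps, geometry=geometry)
        result = compare(
            a, b, ComparisonConfig(alpha=0.05, n_permutations=199, design="two_sample", seed=2)
        )
        assert result.sig_lower[geometry.valid_mask].mean() > 0.9
        assert result.sig_higher.sum() == 0


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_exhaustive_paired_includes_identity(seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(4, 20))
    config = ComparisonConfig(alpha=0.25, n_permutations=16, design="paired", seed=0)
    _, collection = maxt_threshold(d, config)
    t_obs = np.array([sps.ttest_1samp(d[:, j], 0.0).statistic for j in range(20)])
    assert np.any(np.isclose(collection, np.abs(t_obs).max(), atol=1e-10))
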