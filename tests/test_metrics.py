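"""Distribution biomarkers: trimming, IDR, KDE mode, Pearson skew, normality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myot2 import (
    InvalidParameterError,
    MuscleMask,
    PhantomSpec,
    exclude_slices,
    extract_values,
    fit_map,
    interdecile_range,
    kde_mode,
    make_phantom,
    pearson_mode_skew,
    summarize,
    summarize_values,
    test_normality,
    trim_tails,
)


class TestExtract:
    def test_uniform_map_yields_constant_vector(self, noiseless_healthy):
        stack, _, mask = noiseless_healthy
        t2map = fit_map(stack, mask)
        values = extract_values(t2map, mask)
        assert values.size == mask.n_valid
        assert np.allclose(values, 25.0)

    def test_slice_exclusion_removes_that_slices_values(self, noiseless_healthy):
        stack, _, mask = noiseless_healthy
        t2map = fit_map(stack, mask)
        n_full = extract_values(t2map, mask).size
        mask1 = exclude_slices(mask, [0])
        n_less = extract_values(t2map, mask1).size
        assert n_less == n_full - mask.labels[:, :, 0].sum()

    def test_multiset_matches_ground_truth(self, noiseless_severe):
        stack, truth, mask = noiseless_severe
        t2map = fit_map(stack, mask)
        values = np.round(extract_values(t2map, mask), 6)
        expected = truth.t2_field_ms[truth.mask_true]
        assert np.array_equal(np.sort(values), np.sort(expected))


class TestTrim:
    def test_hand_computed_oracle_1_to_1000(self):
        """Linear-interpolation percentiles of 1..1000: P1 = 10.99 and
        P99 = 990.01, so trimming retains exactly 11..990."""
        kept = trim_tails(np.arange(1.0, 1001.0))
        assert np.array_equal(np.sort(kept), np.arange(11.0, 991.0))

    def test_identical_values_untouched(self):
        v = np.full(50, 7.0)
        assert trim_tails(v).size == 50

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            trim_tails(np.array([]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_double_trim_removes_at_most_trim_fraction_again(self, seed):
        """Trimming is not idempotent under the linear-percentile closed-band
        convention: a second pass removes at most the trim fraction again
        (for continuous data it removes ~2% of the already-trimmed sample,
        e.g. 11..990 re-trims to 21..980)."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=rng.integers(50, 500))
        once = trim_tails(v)
        twice = trim_tails(once)
        assert once.size - twice.size <= 0.02 * once.size + 2

    def test_retained_count_lower_bound(self):
        rng = np.random.default_rng(3)
        v = rng.random(987)
        assert trim_tails(v).size >= 0.98 * v.size - 2


class TestIDR:
    def test_uniform_grid_oracle(self):
        # 1..100: P10 = 10.9, P90 = 90.1 under linear interpolation
        assert interdecile_range(np.arange(1.0, 101.0)) == pytest.approx(79.2)

    def test_constant_vector_zero(self):
        assert interdecile_range(np.full(10, 4.2)) == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(InvalidParameterError):
            interdecile_range(np.array([1.0]))

    def test_gaussian_idr_matches_analytic_quantiles(self):
        rng = np.random.default_rng(12)
        draws = rng.standard_normal(1_000_000)
        assert interdecile_range(draws) == pytest.approx(2.5631, abs=0.01)


class TestKdeMode:
    def test_symmetric_unimodal_sample(self):
        rng = np.random.default_rng(1)
        v = rng.normal(30.0, 2.0, 100_000)
        assert kde_mode(v) == pytest.approx(30.0, abs=0.2)

    def test_constant_vector_returns_value_with_warning(self):
        with pytest.warns(UserWarning):
            assert kde_mode(np.full(20, 25.0)) == 25.0

    def test_mixture_mode_is_global_peak(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(25, 1, 90_000), rng.normal(65, 3, 10_000)])
        assert kde_mode(v) == pytest.approx(25.0, abs=1.0)

    def test_mode_within_sample_range(self):
        rng = np.random.default_rng(3)
        v = rng.exponential(10.0, 5000)
        assert v.min() <= kde_mode(v) <= v.max()


class TestPearsonSkew:
    def test_symmetric_sample_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(pearson_mode_skew(rng.normal(0, 1, 100_000))) < 0.05

    def test_right_tailed_mixture_matches_component_oracle(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(25, 1, 90_000), rng.normal(65, 3, 10_000)])
        skew = pearson_mode_skew(v)
        oracle = (v.mean() - kde_mode(v)) / v.std(ddof=1)
        # analytic mixture: mean 29, mode ~ 25, sd ~ sqrt(145.8) -> skew ~ 0.33
        assert skew == pytest.approx((29.0 - 25.0) / math.sqrt(145.8), abs=0.04)
        assert skew == pytest.approx(oracle)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(6)
        v = rng.exponential(5.0, 50_000)
        assert pearson_mode_skew(-v) == pytest.approx(-pearson_mode_skew(v), abs=0.02)

    def test_zero_spread_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(pearson_mode_skew(np.full(20, 3.0)))


class TestNormality:
    def test_exponential_sample_strongly_rejected(self):
        rng = np.random.default_rng(7)
        _, p = test_normality(rng.exponential(1.0, 1000))
        assert p < 0.001

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            test_normality(np.arange(10.0))

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            test_normality(rng.standard_normal(10_000))[1] < 0.05 for _ in range(200)
        )
        assert 0.02 <= rejections / 200 <= 0.09


class TestLocationScale:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-50.0, 50.0))
    def test_equivariance(self, a, b):
        rng = np.random.default_rng(9)
        v = rng.gamma(3.0, 5.0, 5000)
        w = a * v + b
        assert interdecile_range(w) == pytest.approx(a * interdecile_range(v), rel=1e-9)
        assert kde_mode(w) == pytest.approx(a * kde_mode(v) + b, rel=1e-3, abs=1e-2)
        assert pearson_mode_skew(w) == pytest.approx(pearson_mode_skew(v), abs=5e-3)


class TestSummarize:
    def test_degenerate_healthy_phantom(self, noiseless_healthy):
        stack, _, mask = noiseless_healthy
        dist = summarize(fit_map(stack, mask), mask)
        assert dist.idr_ms == 0.0
        assert not dist.skew_defined
        assert dist.n_retained == dist.n_raw  # nothing to trim off a constant

    def test_severe_exceeds_mild(self, acq_tiny):
        results = {}
        for sev in (0.2, 0.9):
            stack, truth = make_phantom(PhantomSpec(seed=21, severity=sev, snr=50.0), acq_tiny)
            mask = MuscleMask(labels=truth.mask_true)
            results[sev] = summarize(fit_map(stack, mask), mask)
        assert results[0.9].idr_ms > results[0.2].idr_ms
        assert results[0.9].pearson_skew > results[0.2].pearson_skew

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(10)
        v = rng.gamma(3.0, 10.0, 5000)
        a = summarize_values(v)
        b = summarize_values(rng.permutation(v))
        assert a.idr_ms == b.idr_ms
        assert a.pearson_skew == b.pearson_skew
        assert a.mode_ms == b.mode_ms

    def test_gaussian_poorly_describes_severe_histogram(self, acq_tiny):
        """Narrow-peak-heavy-tail signature: the empirical mass within
        mode +/- sd exceeds what the fitted Gaussian puts there."""
        from scipy import stats as sps

        stack, truth = make_phantom(PhantomSpec(seed=31, severity=0.9, snr=50.0), acq_tiny)
        mask = MuscleMask(labels=truth.mask_true)
        dist = summarize(fit_map(stack, mask), mask)
        lo, hi = dist.mode_ms - dist.sd_ms, dist.mode_ms + dist.sd_ms
        empirical = np.mean((dist.values_ms >= lo) & (dist.values_ms <= hi))
        gaussian = sps.norm(dist.mean_ms, dist.sd_ms).cdf(hi) - sps.norm(
            dist.mean_ms, dist.sd_ms
        ).cdf(lo)
        assert gaussian < 0.8 * empirical
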