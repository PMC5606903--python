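"""Zero-truncated distributions and the half-normal kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrds_nmix.distributions import (
    ZTBinomialParams,
    ZTPoissonParams,
    halfnormal_kernel,
    ztbinom_mean,
    ztbinom_pmf,
    ztbinom_sample,
    ztpois_mean,
    ztpois_pmf,
    ztpois_sample,
    ztpois_support,
)


class TestZTPoissonPmf:
    def test_closed_form_at_one(self):
        # e^-1 / (1 - e^-1) = 1 / (e - 1)
        assert ztpois_pmf(1, ZTPoissonParams(1.0)) == pytest.approx(
            1.0 / (np.e - 1.0), rel=1e-12
        )

    def test_small_lam_mass_collapses_to_one(self):
        assert ztpois_pmf(1, ZTPoissonParams(1e-12)) == pytest.approx(1.0, abs=1e-9)

    def test_normalization_lam4(self):
        k = np.arange(1, 51)
        assert ztpois_pmf(k, ZTPoissonParams(4.0)).sum() == pytest.approx(
            1.0, abs=1e-12
        )

    @settings(max_examples=25, deadline=None)
    @given(lam=st.floats(0.01, 60.0))
    def test_normalization_property(self, lam):
        params = ZTPoissonParams(lam)
        total = ztpois_pmf(ztpois_support(params), params).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("bad_k", [0, -1, 1.5])
    def test_domain_errors(self, bad_k):
        with pytest.raises(ValueError):
            ztpois_pmf(bad_k, ZTPoissonParams(2.0))

    @pytest.mark.parametrize("bad_lam", [0.0, -1.0, np.nan])
    def test_invalid_lam(self, bad_lam):
        with pytest.raises(ValueError):
            ZTPoissonParams(bad_lam)


class TestZTPoissonSampler:
    def test_matches_pmf_at_lam1(self, rng):
        params = ZTPoissonParams(1.0)
        draws = ztpois_sample(params, rng, size=100_000)
        p1 = float(ztpois_pmf(1, params))
        se = np.sqrt(p1 * (1 - p1) / draws.size)
        assert abs(np.mean(draws == 1) - p1) < 3 * se

    def test_tiny_lam_always_one(self, rng):
        assert np.all(ztpois_sample(ZTPoissonParams(1e-12), rng, size=1000) == 1)

    def test_mean_at_lam20(self, rng):
        params = ZTPoissonParams(20.0)
        draws = ztpois_sample(params, rng, size=100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - ztpois_mean(params)) < 3 * se

    @pytest.mark.parametrize("lam", [0.5, 4.0, 20.0])
    def test_chi_square_goodness_of_fit(self, lam, rng):
        params = ZTPoissonParams(lam)
        draws = ztpois_sample(params, rng, size=100_000)
        support = ztpois_support(params)
        expected = ztpois_pmf(support, params) * draws.size
        observed = np.bincount(draws, minlength=support[-1] + 1)[1:].astype(float)
        # merge sparse cells so all expected counts are >= 5
        keep = expected >= 5
        if (~keep).any():
            expected = np.concatenate([expected[keep], [expected[~keep].sum()]])
            observed = np.concatenate([observed[keep], [observed[~keep].sum()]])
        expected *= observed.sum() / expected.sum()
        stat, pval = stats.chisquare(observed, expected)
        assert pval > 0.001


class TestZTBinomial:
    def test_n1_forces_count_one(self):
        for r in (0.05, 0.5, 1.0):
            assert ztbinom_pmf(1, ZTBinomialParams(r, 1)) == pytest.approx(1.0)

    def test_perfect_detection_counts_all(self):
        assert ztbinom_pmf(7, ZTBinomialParams(1.0, 7)) == pytest.approx(1.0)

    def test_hand_enumeration_n2(self):
        # outcomes {01, 10, 11} -> P(1) = 2/3, P(2) = 1/3 at r = 1/2
        params = ZTBinomialParams(0.5, 2)
        assert ztbinom_pmf(1, params) == pytest.approx(2.0 / 3.0)
        assert ztbinom_pmf(2, params) == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("bad_k", [0, 3])
    def test_domain_errors(self, bad_k):
        with pytest.raises(ValueError):
            ztbinom_pmf(bad_k, ZTBinomialParams(0.5, 2))

    @settings(max_examples=25, deadline=None)
    @given(r=st.floats(0.01, 1.0), n=st.integers(1, 80))
    def test_normalization_property(self, r, n):
        params = ZTBinomialParams(r, n)
        total = ztbinom_pmf(np.arange(1, n + 1), params).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_sampler_n1_and_support(self, rng):
        assert np.all(ztbinom_sample(ZTBinomialParams(0.3, 1), rng, size=500) == 1)
        draws = ztbinom_sample(ZTBinomialParams(0.9, 10), rng, size=2000)
        assert draws.min() >= 1 and draws.max() <= 10

    def test_sampler_matches_pmf(self, rng):
        params = ZTBinomialParams(0.5, 2)
        draws = ztbinom_sample(params, rng, size=100_000)
        p1 = 2.0 / 3.0
        se = np.sqrt(p1 * (1 - p1) / draws.size)
        assert abs(np.mean(draws == 1) - p1) < 3 * se

    @pytest.mark.parametrize("r,n", [(0.3, 5), (0.9, 10), (0.05, 30)])
    def test_chi_square_goodness_of_fit(self, r, n, rng):
        params = ZTBinomialParams(r, n)
        draws = ztbinom_sample(params, rng, size=100_000)
        support = np.arange(1, n + 1)
        expected = ztbinom_pmf(support, params) * draws.size
        observed = np.bincount(draws, minlength=n + 1)[1:]
        keep = expected >= 5
        expected = np.concatenate([expected[keep], [expected[~keep].sum()]]) \
            if (~keep).any() else expected[keep]
        observed = np.concatenate([observed[keep], [observed[~keep].sum()]]) \
            if (~keep).any() else observed[keep]
        expected *= observed.sum() / expected.sum()
        stat, pval = stats.chisquare(observed, expected)
        assert pval > 0.001

    def test_mean_formula(self):
        params = ZTBinomialParams(0.5, 2)
        # E = (1 * 2/3 + 2 * 1/3)
        assert ztbinom_mean(params) == pytest.approx(4.0 / 3.0)


class TestHalfNormalKernel:
    def test_unity_on_the_line(self):
        assert halfnormal_kernel(0.0, 12.3) == pytest.approx(1.0)

    def test_at_one_scale(self):
        assert halfnormal_kernel(65.0, 65.0) == pytest.approx(np.exp(-0.5))

    def test_direct_evaluation(self):
        assert halfnormal_kernel(100.0, 65.0) == pytest.approx(
            np.exp(-10000.0 / 8450.0), rel=1e-12
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            halfnormal_kernel(-1.0, 10.0)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(1.0, 500.0))
    def test_monotone_nonincreasing(self, scale):
        d = np.linspace(0.0, 300.0, 200)
        vals = halfnormal_kernel(d, scale)
        assert np.all(np.diff(vals) <= 0)
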