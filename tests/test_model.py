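"""Log-density components of the augmented posterior."""

import numpy as np
import pytest

import mrds_nmix as mx
from mrds_nmix import _kernels
from mrds_nmix.distributions import (
    ZTBinomialParams,
    ZTPoissonParams,
    ztbinom_logpmf,
    ztpois_logpmf,
)
from mrds_nmix.model import (
    AugmentedState,
    ModelConfig,
    Params,
    group_detect_prob,
    log_likelihood,
    log_posterior,
    log_prior,
    log_process,
    total_abundance,
)
from mrds_nmix.simulator import MISSING_COUNT
from scipy import special
from tests.conftest import make_survey


PARAMS = Params(
    Omega=0.4, lam=2.5, beta0=float(np.log(40.0)), beta1=0.3,
    p0=0.85, r0=0.9, tau=60.0, r_const=0.8,
)


@pytest.fixture()
def tiny():
    data = make_survey(
        [(1, 1, 12.0, 2, 3), (1, 0, 55.0, 1, MISSING_COUNT)]
    )
    state = AugmentedState(
        z=np.array([1, 1, 1]),
        n=np.array([3, 2, 4]),
        d=np.array([12.0, 55.0, 70.0]),
    )
    return data, state


class TestGroupDetectProb:
    def test_on_the_line_equals_p0(self):
        assert group_detect_prob(0.0, 5, PARAMS) == pytest.approx(PARAMS.p0)

    def test_size_effect_switched_off(self):
        p = Params(Omega=0.5, lam=1.0, beta0=np.log(50.0), beta1=0.0, p0=0.9)
        assert group_detect_prob(30.0, 1, p) == pytest.approx(
            group_detect_prob(30.0, 17, p)
        )

    def test_direct_evaluation(self):
        p = Params(Omega=0.5, lam=1.0, beta0=np.log(65.0), beta1=0.25, p0=1.0)
        assert group_detect_prob(100.0, 1, p) == pytest.approx(
            np.exp(-10000.0 / (2 * 65.0**2)), rel=1e-12
        )


class TestLogLikelihood:
    def test_termwise_oracle(self, tiny):
        """Matches a brute-force sum of Bernoulli and zero-truncated
        binomial terms computed with the distributions module."""
        data, state = tiny
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=3)

        expected = 0.0
        # observed rows
        for i, (y, c) in enumerate(zip(data.detections, data.counts)):
            p = group_detect_prob(state.d[i], state.n[i], PARAMS)
            r = PARAMS.r0 * np.exp(-state.d[i] ** 2 / (2 * PARAMS.tau**2))
            for j in range(2):
                expected += np.log(p) if y[j] == 1 else np.log1p(-p)
                if c[j] != MISSING_COUNT:
                    expected += float(
                        ztbinom_logpmf(c[j], ZTBinomialParams(r, int(state.n[i])))
                    )
        # augmented row (z=1, no detections)
        p_aug = group_detect_prob(state.d[2], state.n[2], PARAMS)
        expected += 2 * np.log1p(-p_aug)

        assert log_likelihood(PARAMS, state, data, cfg) == pytest.approx(
            expected, rel=1e-12
        )

    def test_constant_r_variant(self, tiny):
        data, state = tiny
        cfg = ModelConfig(variant="mrds_nmix_const_r", M=3)
        ll = log_likelihood(PARAMS, state, data, cfg)
        # recompute with r = r_const
        expected = 0.0
        for i, (y, c) in enumerate(zip(data.detections, data.counts)):
            p = group_detect_prob(state.d[i], state.n[i], PARAMS)
            for j in range(2):
                expected += np.log(p) if y[j] == 1 else np.log1p(-p)
                if c[j] != MISSING_COUNT:
                    expected += float(
                        ztbinom_logpmf(
                            c[j], ZTBinomialParams(PARAMS.r_const, int(state.n[i]))
                        )
                    )
        p_aug = group_detect_prob(state.d[2], state.n[2], PARAMS)
        expected += 2 * np.log1p(-p_aug)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_reduced_variant_ignores_counts(self, tiny):
        data, state = tiny
        cfg = ModelConfig(variant="mrds_reduced", M=3)
        base = log_likelihood(PARAMS, state, data, cfg)
        # same detection data with different counts: identical density
        shuffled = make_survey([(1, 1, 12.0, 1, 1), (1, 0, 55.0, 1, MISSING_COUNT)])
        assert log_likelihood(PARAMS, state, shuffled, cfg) == pytest.approx(base)

    def test_detection_without_membership_impossible(self, tiny):
        data, state = tiny
        state.z = np.array([0, 1, 1])  # row 0 was detected but z=0
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=3)
        assert log_likelihood(PARAMS, state, data, cfg) == -np.inf

    def test_count_exceeding_size_invalid(self, tiny):
        data, state = tiny
        state.n = np.array([2, 2, 4])  # row 0 has count 3 > n=2
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=3)
        assert log_likelihood(PARAMS, state, data, cfg) == -np.inf

    def test_perfect_observation_has_unit_likelihood(self):
        data = make_survey([(1, 1, 5.0, 3, 3)])
        state = AugmentedState(z=np.array([1]), n=np.array([3]), d=np.array([5.0]))
        params = Params(
            Omega=1.0, lam=3.0, beta0=np.log(1e8), beta1=0.0,
            p0=1.0, r0=1.0, tau=1e8, r_const=1.0,
        )
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=1)
        assert log_likelihood(params, state, data, cfg) == pytest.approx(0.0, abs=1e-8)


class TestLogProcess:
    def test_hand_computed_two_rows(self):
        state = AugmentedState(
            z=np.array([1, 0]), n=np.array([2, 1]), d=np.array([10.0, 90.0])
        )
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=2, w=100.0)
        expected = (
            2 * np.log(1 / 100.0)
            + np.log(PARAMS.Omega)
            + np.log1p(-PARAMS.Omega)
            + float(ztpois_logpmf(2, ZTPoissonParams(PARAMS.lam)))
            + float(ztpois_logpmf(1, ZTPoissonParams(PARAMS.lam)))
        )
        assert log_process(PARAMS, state, cfg) == pytest.approx(expected, rel=1e-12)

    def test_certain_inclusion_contributes_nothing(self):
        state = AugmentedState(
            z=np.array([1, 1]), n=np.array([1, 1]), d=np.array([1.0, 2.0])
        )
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=2, w=100.0)
        p1 = Params(Omega=1.0, lam=2.5, beta0=1.0, beta1=0.0, p0=0.5)
        expected = 2 * np.log(1 / 100.0) + 2 * float(
            ztpois_logpmf(1, ZTPoissonParams(2.5))
        )
        assert log_process(p1, state, cfg) == pytest.approx(expected)

    def test_distance_at_strip_edge_outside_support(self):
        state = AugmentedState(
            z=np.array([1]), n=np.array([1]), d=np.array([100.0])
        )
        cfg = ModelConfig(variant="mrds_nmix_distance_r", M=1, w=100.0)
        assert log_process(PARAMS, state, cfg) == -np.inf


class TestLogPrior:
    def test_finite_at_default_point(self):
        cfg = ModelConfig(variant="mrds_nmix_distance_r")
        assert np.isfinite(log_prior(PARAMS, cfg))

    @pytest.mark.parametrize(
        "bad",
        [
            {"tau": -1.0},
            {"lam": 500.0},
            {"Omega": 0.0},
            {"p0": 1.5},
        ],
    )
    def test_out_of_support(self, bad):
        cfg = ModelConfig(variant="mrds_nmix_distance_r")
        params = Params(**{**PARAMS.__dict__, **bad})
        assert log_prior(params, cfg) == -np.inf

    def test_bounds_overridable(self):
        cfg = ModelConfig(
            variant="mrds_nmix_distance_r", priors={"lam_max": 1000.0}
        )
        params = Params(**{**PARAMS.__dict__, "lam": 500.0})
        assert np.isfinite(log_prior(params, cfg))


class TestTotalAbundance:
    def test_no_members_no_animals(self):
        state = AugmentedState(
            z=np.zeros(4, dtype=int), n=np.array([3, 1, 2, 9]), d=np.zeros(4)
        )
        assert total_abundance(state) == 0

    def test_arithmetic(self):
        state = AugmentedState(
            z=np.array([1, 1, 0]), n=np.array([3, 4, 99]), d=np.zeros(3)
        )
        assert total_abundance(state) == 7

    def test_full_inclusion_recovers_truth(self, scenarios, rng):
        _, truth = mx.simulate_dataset(scenarios[4], rng)
        state = AugmentedState(
            z=np.ones_like(truth.sizes), n=truth.sizes, d=truth.distances
        )
        assert total_abundance(state) == truth.n_total


@pytest.mark.parametrize(
    "variant", ["mrds_nmix_const_r", "mrds_nmix_distance_r", "mrds_reduced"]
)
def test_compiled_logpost_matches_reference(scenarios, variant, rng):
    """The numba kernel's full log posterior agrees term-for-term with the
    pure-Python reference on random augmented states."""
    data, _ = mx.simulate_dataset(scenarios[1], rng)
    n_obs = len(data)
    M = 2 * n_obs
    cfg = ModelConfig(variant=variant, M=M, w=100.0)
    code = {"mrds_nmix_const_r": 0, "mrds_nmix_distance_r": 1, "mrds_reduced": 2}[
        variant
    ]
    lfact = special.gammaln(np.arange(2048) + 1.0)
    y = np.zeros((M, 2), dtype=np.int64)
    y[:n_obs] = data.detections
    c = np.full((M, 2), -1, dtype=np.int64)
    c[:n_obs] = data.counts

    for trial in range(5):
        z = np.ones(M, dtype=np.int64)
        z[n_obs:] = rng.integers(0, 2, M - n_obs)
        n = np.maximum(data.max_counts.max(), 1) + rng.integers(0, 4, M)
        d = np.empty(M)
        d[:n_obs] = data.distances
        d[n_obs:] = rng.uniform(0, 100.0, M - n_obs)
        params = Params(
            Omega=rng.uniform(0.2, 0.8),
            lam=rng.uniform(0.5, 5.0),
            beta0=rng.uniform(2.0, 4.5),
            beta1=rng.uniform(-0.5, 1.0),
            p0=rng.uniform(0.5, 0.99),
            r0=rng.uniform(0.5, 0.99),
            tau=rng.uniform(30.0, 120.0),
            r_const=rng.uniform(0.5, 0.99),
        )
        state = AugmentedState(z=z, n=n.astype(np.int64), d=d)
        ref = log_posterior(params, state, data, cfg)
        ker = _kernels.full_logpost(
            z, n.astype(np.int64), d, y, c, params.as_array(), n_obs, M,
            100.0, code, cfg.priors.beta_sd, cfg.priors.lam_max,
            cfg.priors.resolved_tau_max(100.0), cfg.priors.beta1_min, lfact,
        )
        if np.isinf(ref):
            assert np.isinf(ker) and ker < 0
        else:
            assert ker == pytest.approx(ref, rel=1e-9, abs=1e-9)


def test_model_config_serialization_round_trip():
    cfg = ModelConfig(variant="mrds_nmix_const_r", M=333, w=80.0,
                      priors={"beta_sd": 5.0, "lam_max": 100.0})
    back = ModelConfig.from_yaml(cfg.to_yaml())
    assert back == cfg
    assert "mrds_nmix_const_r" in cfg.to_json()
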