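"""Shared fixtures.

Heavy MCMC runs are session-scoped so that module-level tests and the
acceptance suite assert on the same cached results instead of refitting.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import mrds_nmix as mx


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scenarios():
    return mx.scenario_table()


@pytest.fixture(scope="session")
def perfect_scenario():
    """Detection kernels ~1 everywhere and perfect counts: every group is
    seen by both observers and counted exactly."""
    return mx.Scenario(
        lam=4.0, beta0=float(np.log(1e6)), beta1=0.25, tau=1e6,
        p0=1.0, r0=1.0, n_groups=200, strip_width=100.0,
    )


@pytest.fixture(scope="session")
def perfect_fit(perfect_scenario):
    """MRDS-Nmix fit to a fully observed survey."""
    data, truth = mx.simulate_dataset(perfect_scenario, np.random.default_rng(7))
    fit = mx.fit(
        data,
        mx.ModelConfig(variant="mrds_nmix_distance_r"),
        mx.SamplerConfig(seed=21),
    )
    return fit, truth, data


@pytest.fixture(scope="session")
def perfect_counts_pair(scenarios):
    """MRDS-Nmix and reduced MRDS fitted to the same survey with perfect
    counts (r0 = 1, tau huge) but imperfect group detection."""
    scn5 = scenarios[4]
    scn = replace(scn5, r0=1.0, tau=1e6, scenario_id=None)
    data, truth = mx.simulate_dataset(scn, np.random.default_rng(31))
    scfg = mx.SamplerConfig(seed=5)
    f_nmix = mx.fit(data, mx.ModelConfig(variant="mrds_nmix_distance_r"), scfg)
    f_mrds = mx.fit(data, mx.ModelConfig(variant="mrds_reduced"), scfg)
    return f_nmix, f_mrds, truth


@pytest.fixture(scope="session")
def doubling_m_pair(scenarios):
    """The same scenario-1 survey fitted with M = 3 n_obs and M = 6 n_obs."""
    data, truth = mx.simulate_dataset(scenarios[0], np.random.default_rng(17))
    scfg = mx.SamplerConfig(seed=9)
    f3 = mx.fit(data, mx.ModelConfig(variant="mrds_nmix_distance_r"), scfg)
    f6 = mx.fit(
        data,
        mx.ModelConfig(variant="mrds_nmix_distance_r", M=6 * len(data)),
        scfg,
    )
    return f3, f6, truth


@pytest.fixture(scope="session")
def recovery_fits(scenarios):
    """Two independent scenario-1 replicates fitted with default chains,
    for parameter-recovery checks."""
    out = []
    for rep in range(2):
        data, truth = mx.simulate_dataset(
            scenarios[0], np.random.default_rng(100 + rep)
        )
        fit = mx.fit(
            data,
            mx.ModelConfig(variant="mrds_nmix_distance_r"),
            mx.SamplerConfig(seed=200 + rep),
        )
        out.append((fit, truth))
    return out


def mcse(fit, name="N"):
    """Monte-Carlo standard error of a posterior mean."""
    draws = np.asarray(fit.draws[name], dtype=float)
    ess = fit.ess.get(name)
    if ess is None or not np.isfinite(ess) or ess < 1:
        ess = draws.size
    return float(draws.std(ddof=1) / np.sqrt(ess))


def make_survey(rows):
    """Build a SurveyDataset from (y1, y2, distance, count1, count2) rows."""
    import pandas as pd

    df = pd.DataFrame(rows, columns=["y1", "y2", "distance", "count1", "count2"])
    df.insert(0, "group_id", np.arange(len(df)))
    return mx.SurveyDataset(table=df, strip_width=100.0)


TINY_PARAMS = mx.Params(
    Omega=0.45, lam=2.0, beta0=float(np.log(45.0)), beta1=0.3,
    p0=0.85, r0=0.9, tau=60.0, r_const=0.9,
)


def z_conditional_enumeration_gap():
    """|kernel z full conditional - two-term enumeration| on a one-row
    augmented instance, evaluated through the reference densities."""
    from mrds_nmix import _kernels

    data = make_survey([(1, 1, 10.0, 2, 2)])
    cfg = mx.ModelConfig(variant="mrds_nmix_distance_r", M=2)
    weights = []
    for z_aug in (0, 1):
        state = mx.AugmentedState(
            z=np.array([1, z_aug]), n=np.array([2, 3]), d=np.array([10.0, 62.0])
        )
        lp = mx.log_process(TINY_PARAMS, state, cfg) + mx.log_likelihood(
            TINY_PARAMS, state, data, cfg
        )
        weights.append(np.exp(lp))
    enumerated = weights[1] / (weights[0] + weights[1])
    p_aug = mx.group_detect_prob(62.0, 3, TINY_PARAMS)
    kernel = _kernels.z_full_conditional(TINY_PARAMS.Omega, p_aug)
    return abs(kernel - enumerated)


@pytest.fixture(scope="session")
def tiny_tv():
    """Latent-only chain on an enumerable 3-row instance versus exact
    per-row posteriors over (z, n), with latent distance integrated by
    quadrature.  Returns per-row total-variation distances."""
    from mrds_nmix.distributions import (
        ZTBinomialParams, ZTPoissonParams, ztbinom_pmf, ztpois_pmf,
        ztpois_support,
    )
    from mrds_nmix.mcmc import SamplerConfig
    from mrds_nmix.model import ModelConfig
    from mrds_nmix.simulator import MISSING_COUNT

    params = TINY_PARAMS
    data = make_survey([(1, 0, 20.0, 2, MISSING_COUNT)])
    mcfg = ModelConfig(variant="mrds_nmix_distance_r", M=3)
    scfg = SamplerConfig(n_chains=2, n_iter=42_000, n_burn=2_000, thin=2, seed=77)
    fit = mx.fit(data, mcfg, scfg, init=params, sample_params=False)
    lat = np.asarray(fit.draws["_latent"]).reshape(-1, 6)
    z_draws, n_draws = lat[:, :3], lat[:, 3:]

    support = ztpois_support(ZTPoissonParams(params.lam))
    prior_n = ztpois_pmf(support, ZTPoissonParams(params.lam))
    x, wq = np.polynomial.legendre.leggauss(256)
    dgrid = 50.0 * (x + 1.0)  # (0, 100)

    tvs = []
    # observed row: z = 1, the recorded count 2 floors the size support
    p_obs = mx.group_detect_prob(20.0, support.astype(float), params)
    r_obs = params.r0 * np.exp(-(20.0**2) / (2 * params.tau**2))
    w_obs = np.array(
        [
            prior_n[i] * p_obs[i] * (1 - p_obs[i])
            * (float(ztbinom_pmf(2, ZTBinomialParams(r_obs, int(k)))) if k >= 2 else 0.0)
            for i, k in enumerate(support)
        ]
    )
    w_obs /= w_obs.sum()
    emp = np.array([np.mean(n_draws[:, 0] == k) for k in support])
    tvs.append(0.5 * np.abs(emp - w_obs).sum())

    # augmented rows: joint over (z, n), distance marginalised by quadrature
    miss = np.empty(len(support))
    for i, k in enumerate(support):
        pk = mx.group_detect_prob(dgrid, float(k), params)
        miss[i] = 0.5 * np.sum(wq * (1 - pk) ** 2)
    w_joint = np.concatenate(
        [(1 - params.Omega) * prior_n, params.Omega * prior_n * miss]
    )
    w_joint /= w_joint.sum()
    for row in (1, 2):
        emp = np.concatenate(
            [
                [np.mean((z_draws[:, row] == z) & (n_draws[:, row] == k)) for k in support]
                for z in (0, 1)
            ]
        )
        tvs.append(0.5 * np.abs(emp - w_joint).sum())
    return tvs
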