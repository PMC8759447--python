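"""Sampler correctness: conjugate oracle, prior reproduction, diagnostics."""

import numpy as np
import pytest

from baskborrow import (
    AnalysisConfig,
    HalfNormalPrior,
    MCMCSettings,
    PatientRecord,
    SubtrialData,
    effective_sample_size,
    fit_joint_operational_model,
    fit_linear_model,
    fit_subtrial_model,
    half_normal_quantile,
    split_rhat,
)
from baskborrow.inference import _run_chains


@pytest.mark.parametrize(
    "scale, p, expected",
    [
        (1.0, 0.5, 0.674),
        (1.0, 0.975, 2.241),
        (1.0, 0.025, 0.031),
        (0.125, 0.5, 0.084),
        (0.125, 0.975, 0.280),
        (0.125, 0.025, 0.004),
    ],
)
def test_half_normal_quantiles(scale, p, expected):
    assert half_normal_quantile(HalfNormalPrior(scale), p) == pytest.approx(
        expected, abs=5e-4
    )


def test_half_normal_scale_family(rng):
    base = HalfNormalPrior(1.0)
    for z in (0.125, 0.5, 3.0):
        for p in rng.uniform(0.01, 0.99, 5):
            assert HalfNormalPrior(z).quantile(p) == pytest.approx(
                z * base.quantile(p), rel=1e-12
            )


@pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
def test_half_normal_quantile_domain(p):
    with pytest.raises(ValueError):
        half_normal_quantile(HalfNormalPrior(1.0), p)


def _conjugate_oracle(X, y, sigma, prior_mean, prior_var):
    """Closed-form normal posterior for known-sigma Gaussian regression."""
    A = X.T @ X / sigma**2 + np.diag(1.0 / prior_var)
    cov = np.linalg.inv(A)
    mean = cov @ (X.T @ y / sigma**2 + prior_mean / prior_var)
    return mean[-1], np.sqrt(cov[-1, -1])


def test_mcmc_matches_conjugate_normal_posterior(reduced_config, rng):
    n, sigma = 20, 0.4
    T = np.repeat([0.0, 1.0], n // 2)
    X = np.column_stack([np.ones(n), T])
    y = 1.0 + 0.5 * T + rng.normal(0, sigma, n)
    pm, pv = np.zeros(2), np.array([25.0, 100.0])
    post = fit_linear_model(X, y, pm, pv, reduced_config, sigma_fixed=sigma, seed=7)
    mean, sd = _conjugate_oracle(X, y, sigma, pm, pv)
    mcse = post.sd / np.sqrt(post.ess)
    assert post.mean == pytest.approx(mean, abs=2 * mcse)
    assert post.sd == pytest.approx(sd, rel=0.05)


def test_prior_only_sampling_reproduces_vague_prior(reduced_config):
    cfg = AnalysisConfig(mcmc=MCMCSettings(chains=2, iterations=30_000, burn_in=1_000))
    post = fit_linear_model(
        np.empty((0, 2)), np.empty(0), np.zeros(2), np.array([25.0, 100.0]), cfg, seed=3
    )
    assert post.mean == pytest.approx(0.0, abs=0.2)
    assert post.sd == pytest.approx(10.0, rel=0.02)
    # 95% prior interval of N(0, 10^2): +/- 19.600
    assert post.quantile(0.975) == pytest.approx(19.600, rel=0.02)
    assert post.quantile(0.025) == pytest.approx(-19.600, rel=0.02)


def _two_arm_subtrial(vals0, vals1, label="s"):
    recs = [PatientRecord(0, (), v) for v in vals0] + [
        PatientRecord(1, (), v) for v in vals1
    ]
    return SubtrialData(label, recs)


def test_symmetric_arms_center_posterior_at_zero(reduced_config, rng):
    vals = rng.normal(1.0, 0.4, 8)
    sub = _two_arm_subtrial(vals, vals)  # byte-identical arms
    post = fit_subtrial_model(sub, (0.0, 10.0), reduced_config, seed=11)
    assert abs(post.mean) < 0.5 * post.sd


def test_posterior_contracts_with_sample_size(reduced_config, rng):
    sds = []
    for n in (8, 16, 32):
        v0 = rng.normal(0.0, 0.4, n)
        v1 = rng.normal(0.5, 0.4, n)
        post = fit_subtrial_model(
            _two_arm_subtrial(v0, v1), (0.0, 10.0), reduced_config, seed=5
        )
        sds.append(post.sd)
    assert sds[0] > sds[1] > sds[2]


def test_vague_prior_insensitivity(rng):
    cfg = AnalysisConfig(mcmc=MCMCSettings(chains=2, iterations=8_000, burn_in=1_000))
    sub = _two_arm_subtrial(rng.normal(0, 0.4, 10), rng.normal(0.5, 0.4, 10))
    a = fit_subtrial_model(sub, (0.0, 10.0), cfg, seed=9)
    b = fit_subtrial_model(sub, (0.0, 1_000.0), cfg, seed=9)
    assert abs(a.mean - b.mean) < 0.01


def test_degenerate_prior_dominates(reduced_config, rng):
    sub = _two_arm_subtrial(rng.normal(0, 0.4, 10), rng.normal(2.0, 0.4, 10))
    post = fit_subtrial_model(sub, (-1.0, 1e-4), reduced_config, seed=2)
    assert post.mean == pytest.approx(-1.0, abs=0.01)


def test_joint_fit_recovers_simulated_truth(effect_trial, reduced_config):
    posteriors = fit_joint_operational_model(effect_trial, reduced_config, seed=21)
    assert set(posteriors) == set(effect_trial.labels)
    for post in posteriors.values():
        assert abs(post.mean - 0.45) < 3 * post.sd


def test_diagnostics_match_arviz():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(0)
    # an AR(1) chain with known autocorrelation
    chains = np.empty((2, 4000))
    for c in range(2):
        x = 0.0
        for i in range(4000):
            x = 0.6 * x + rng.normal()
            chains[c, i] = x
    ours_rhat = split_rhat(chains)
    ours_ess = effective_sample_size(chains)
    ref_rhat = float(az.rhat(chains[None].transpose(1, 2, 0)).x if hasattr(az.rhat(chains), "x") else az.rhat(chains))
    ref_ess = float(az.ess(chains))
    assert ours_rhat == pytest.approx(ref_rhat, abs=0.01)
    assert ours_ess == pytest.approx(ref_ess, rel=0.15)


def test_density_evaluator_integrates_to_one(effect_trial, reduced_config):
    post = fit_subtrial_model(
        effect_trial.subtrials[0], (0.0, 10.0), reduced_config, seed=4
    )
    grid = np.linspace(post.mean - 10 * post.sd, post.mean + 10 * post.sd, 4001)
    total = np.trapezoid(post.density(grid), grid)
    assert 0.99 < total < 1.01
    post.use_kde()
    total_kde = np.trapezoid(post.density(grid), grid)
    assert 0.98 < total_kde < 1.02


def test_hm_prior_only_reproduces_tau_prior():
    """Prior-only Gibbs on the exchangeable hierarchy reproduces HN(0.125)."""
    cfg = AnalysisConfig(mcmc=MCMCSettings(chains=2, iterations=250_000, burn_in=10_000))
    K, p = 6, 4
    _, _, _, hyper = _run_chains(
        np.zeros((K, p, p)),
        np.zeros((K, p)),
        np.empty((0, p)),
        np.empty(0),
        np.zeros(K + 1, dtype=np.int64),
        cfg,
        theta_mode=1,
        tau_scale=0.125,
        gamma_random=False,
        seed=5,
    )
    tau = hyper[:, :, 1].ravel()
    assert np.median(tau) == pytest.approx(0.084, rel=0.02)
    assert np.quantile(tau, 0.975) == pytest.approx(0.280, rel=0.02)
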