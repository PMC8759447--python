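"""Spike-and-slab CPPs, distance-to-weight transform, MPP combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baskborrow import (
    AnalysisConfig,
    MPPrior,
    MarginalCPP,
    PosteriorDensity,
    SpikeSlabPrior,
    ValidationError,
    WeightVector,
    analyze_proposed,
    combine_mpp,
    fit_subtrial_model,
    fit_with_mpp,
    generate_trial,
    marginal_cpp_moments,
    sample_spike_slab,
    weights_from_distances,
    SCENARIOS,
)
from baskborrow.data import BasketTrialData, SubtrialData
from baskborrow.discrepancy import build_discrepancy_matrix

SLAB_E_INV2 = (1.0 / 0.01 - 1.0) / 0.99  # exact E[1/nu^2] under U(0.01, 1) = 100


def test_spike_slab_validation():
    with pytest.raises(ValidationError):
        SpikeSlabPrior(B1=1.0, B2=0.5)
    with pytest.raises(ValidationError):
        SpikeSlabPrior(S=0.5)
    with pytest.raises(ValidationError):
        SpikeSlabPrior(w=1.2)


def test_pure_spike_draws_all_equal_S():
    prior = SpikeSlabPrior(w=0.0)
    assert np.all(sample_spike_slab(prior, 1000, seed=0) == 100.0)


def test_pure_slab_draws_and_inverse_square_mean():
    prior = SpikeSlabPrior(w=1.0)
    draws = sample_spike_slab(prior, 1_000_000, seed=1)
    assert np.all((draws >= 0.01) & (draws <= 1.0))
    # E[1/nu^2] = (1/(B2-B1)) (1/B1 - 1/B2) = 100 exactly
    assert np.mean(1.0 / draws**2) == pytest.approx(SLAB_E_INV2, rel=0.03)
    assert prior.mean_inv_nu_sq() == pytest.approx(100.0, abs=2e-12)


def test_mixture_proportion():
    prior = SpikeSlabPrior(w=0.5)
    draws = sample_spike_slab(prior, 1_000_000, seed=2)
    assert np.mean(draws == 100.0) == pytest.approx(0.5, abs=0.002)


def test_spike_slab_reproducible():
    prior = SpikeSlabPrior(w=0.3)
    assert np.array_equal(
        sample_spike_slab(prior, 100, seed=7), sample_spike_slab(prior, 100, seed=7)
    )


def _post(rng, mean=0.5, sd=0.1, n=20_000):
    return PosteriorDensity(draws=rng.normal(mean, sd, n))


def test_cpp_moments_pure_spike(rng):
    post = _post(rng)
    cpp = marginal_cpp_moments(post, SpikeSlabPrior(w=0.0), label="a")
    assert cpp.lam == pytest.approx(post.mean)
    assert cpp.xi2 == pytest.approx(post.sd**2 + 1e-4)


def test_cpp_moments_pure_slab_discards_information(rng):
    post = _post(rng)
    cpp = marginal_cpp_moments(post, SpikeSlabPrior(w=1.0), label="a")
    assert cpp.xi2 == pytest.approx(post.sd**2 + 100.0, rel=1e-9)


def test_cpp_converges_to_source_posterior_as_spike_grows(rng):
    post = _post(rng)
    for S in (1e2, 1e4, 1e6):
        cpp = marginal_cpp_moments(post, SpikeSlabPrior(S=S, w=0.0), label="a")
        assert cpp.lam == post.mean
    assert cpp.xi2 == pytest.approx(post.sd**2, rel=1e-4)


def test_cpp_monte_carlo_path_matches_analytic(rng):
    post = _post(rng)
    prior = SpikeSlabPrior(w=0.3)
    analytic = marginal_cpp_moments(post, prior, label="a")
    n = 400_000
    mc = marginal_cpp_moments(post, prior, label="a", method="mc", n_draws=n, seed=9)
    assert mc.lam == pytest.approx(analytic.lam, abs=0.05)
    # variance se estimated by batching the heavy-tailed slab contribution
    rng2 = np.random.default_rng(99)
    batches = [
        marginal_cpp_moments(
            post, prior, label="a", method="mc", n_draws=n // 20, seed=int(s)
        ).xi2
        for s in rng2.integers(2**31, size=20)
    ]
    se = np.std(batches, ddof=1) / np.sqrt(20)  # se of the full-n estimate
    assert abs(mc.xi2 - analytic.xi2) < 2 * se + 1e-6


def test_equal_distances_give_exactly_uniform_weights():
    wv = weights_from_distances({"a": 0.4, "b": 0.4, "c": 0.4, "d": 0.4, "e": 0.4}, 0.15)
    assert all(w == pytest.approx(0.2, abs=1e-15) for w in wv.weights.values())


def test_weight_transform_worked_example():
    wv = weights_from_distances({"a": 0.1, "b": 0.5}, 0.15)
    assert wv.weights["a"] == pytest.approx(0.935, abs=5e-4)
    assert wv.weights["b"] == pytest.approx(0.065, abs=5e-4)


def test_large_s0_limit_is_uniform():
    wv = weights_from_distances({"a": 0.0, "b": 0.37, "c": 0.99}, 1e6)
    for w in wv.weights.values():
        assert w == pytest.approx(1.0 / 3.0, abs=1e-5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    d=st.lists(st.floats(0, 1), min_size=2, max_size=6, unique=True),
    s0=st.floats(0.05, 2.0),
)
def test_weights_sum_to_one_and_decrease_in_distance(d, s0):
    from hypothesis import assume

    gaps = np.diff(np.sort(d))
    assume(gaps.size == 0 or gaps.min() > 1e-6)
    labels = [f"s{i}" for i in range(len(d))]
    wv = weights_from_distances(dict(zip(labels, d)), s0)
    assert sum(wv.weights.values()) == pytest.approx(1.0, abs=1e-12)
    order = sorted(zip(d, labels))
    weights_sorted = [wv.weights[lab] for _, lab in order]
    assert all(a > b for a, b in zip(weights_sorted, weights_sorted[1:]))


def test_weight_transform_edge_cases():
    with pytest.raises(ValidationError):
        weights_from_distances({}, 0.15)
    with pytest.raises(ValidationError):
        weights_from_distances({"a": 0.5}, -1.0)
    with pytest.raises(ValidationError):
        weights_from_distances({"a": 1.5}, 0.15)
    # single source: the weight is the scalar 1
    assert weights_from_distances({"a": 0.8}, 0.15).weights == {"a": 1.0}


def test_combine_single_source_is_identity():
    cpp = MarginalCPP("a", lam=0.4, xi2=0.04)
    mpp = combine_mpp([cpp], WeightVector({"a": 1.0}, 0.15))
    assert (mpp.mean, mpp.var) == (0.4, 0.04)


def test_combine_two_sources_equal_weights():
    cpps = [MarginalCPP("a", 0.4, 0.04), MarginalCPP("b", 0.6, 0.04)]
    mpp = combine_mpp(cpps, WeightVector({"a": 0.5, "b": 0.5}, 0.15))
    assert mpp.mean == pytest.approx(0.5)
    assert mpp.var == pytest.approx(0.02)


@pytest.mark.parametrize("K", [3, 5, 7])
def test_identical_sources_variance_shrinks_as_one_over_Km1(K):
    lam, xi2 = 0.45, 0.09
    cpps = [MarginalCPP(f"s{k}", lam, xi2) for k in range(K - 1)]
    weights = WeightVector({f"s{k}": 1.0 / (K - 1) for k in range(K - 1)}, 0.15)
    mpp = combine_mpp(cpps, weights)
    assert mpp.mean == pytest.approx(lam)
    assert mpp.var == pytest.approx(xi2 / (K - 1))


def test_combine_label_mismatch_rejected():
    with pytest.raises(ValidationError):
        combine_mpp([MarginalCPP("a", 0.0, 1.0)], WeightVector({"b": 1.0}, 0.15))


def test_vague_mpp_matches_standalone_fit(reduced_config):
    trial = generate_trial(SCENARIOS[5], seed=8)
    target = trial.subtrials[2]
    standalone = fit_subtrial_model(target, (0.0, 10.0), reduced_config, seed=13)
    vague = fit_with_mpp(target, MPPrior(0.0, 1e4), reduced_config, seed=13)
    assert abs(vague.mean - standalone.mean) < 0.02


def test_point_mass_mpp_dominates(reduced_config):
    trial = generate_trial(SCENARIOS[5], seed=8)
    post = fit_with_mpp(trial.subtrials[0], MPPrior(2.0, 1e-8), reduced_config, seed=3)
    assert post.mean == pytest.approx(2.0, abs=1e-3)


def test_robust_posterior_resists_outlier_source(reduced_config):
    """Slab down-weighting: a 10-sd-displaced source shifts the robust
    posterior less than the no-safeguard weighted average would."""
    trial = generate_trial(SCENARIOS[9], seed=77)
    target = trial.subtrials[0]
    clean = fit_subtrial_model(target, (0.0, 10.0), reduced_config, seed=19)
    lam0, xi0 = clean.mean, clean.sd
    shift = 10.0 * xi0
    # two sources: one consistent, one displaced by 10 sd
    from baskborrow.discrepancy import hellinger_normal

    sources = {"good": (lam0, xi0), "bad": (lam0 + shift, xi0)}
    dists = {
        lab: hellinger_normal(lam0, xi0, m, s) for lab, (m, s) in sources.items()
    }
    wv = weights_from_distances(dists, 0.15)
    cpps = [
        marginal_cpp_moments(
            PosteriorDensity(draws=np.random.default_rng(5).normal(m, s, 20000)),
            SpikeSlabPrior(w=dists[lab]),
            label=lab,
        )
        for lab, (m, s) in sources.items()
    ]
    robust_post = fit_with_mpp(target, combine_mpp(cpps, wv), reduced_config, seed=23)
    # no-safeguard: spike-only CPPs and plain averaging of source means
    naive_prior_mean = np.mean([m for m, _ in sources.values()])
    naive_prior_var = np.mean([s**2 for _, s in sources.values()]) / 2
    naive_post = fit_with_mpp(
        target, MPPrior(naive_prior_mean, naive_prior_var), reduced_config, seed=23
    )
    assert abs(robust_post.mean - lam0) < abs(naive_post.mean - lam0)


def _cloned_trial(trial, K=6):
    base = trial.subtrials[0]
    subs = [SubtrialData(label=str(k + 1), records=list(base.records)) for k in range(K)]
    return BasketTrialData(subs)


def test_perfect_consistency_tightens_every_posterior(reduced_config):
    trial = _cloned_trial(generate_trial(SCENARIOS[5], seed=15))
    res = analyze_proposed(trial, reduced_config, seed=31, diagnostics=False)
    standalone = {
        s.label: fit_subtrial_model(s, (0.0, 10.0), reduced_config, seed=31)
        for s in trial.subtrials
    }
    for lab in trial.labels:
        assert res.posteriors[lab].sd < standalone[lab].sd


def test_two_subtrial_weights_are_scalar_one(reduced_config):
    trial = BasketTrialData(generate_trial(SCENARIOS[5], seed=15).subtrials[:2])
    res = analyze_proposed(trial, reduced_config, seed=3, diagnostics=False)
    for wv in res.weight_vectors.values():
        assert list(wv.weights.values()) == [1.0]


def test_single_subtrial_falls_back_with_warning(reduced_config):
    trial = BasketTrialData(generate_trial(SCENARIOS[5], seed=15).subtrials[:1])
    with pytest.warns(UserWarning, match="stand-alone"):
        res = analyze_proposed(trial, reduced_config, seed=3, diagnostics=False)
    assert res.distance_matrix is None
    assert len(res.posteriors) == 1


def test_consistent_nulls_attract_weight_under_conflict(fast_config):
    """In the mixed-null scenario, the analysis of a null subtrial puts more
    weight on the other null subtrial than on a strong-effect one."""
    from baskborrow.inference import fit_joint_operational_model

    scenario = SCENARIOS[8]  # theta = (0.33, 0, 0.82, 0.90, 0, 0.83)
    wins = 0
    reps = 200
    for m in range(reps):
        trial = generate_trial(scenario, seed=10_000 + m)
        posts = fit_joint_operational_model(
            trial, fast_config, seed=20_000 + m, diagnostics=False
        )
        dmat = build_discrepancy_matrix(posts)
        wv = weights_from_distances(dmat.distances_to("2"), fast_config.s0)
        if wv.weights["5"] > wv.weights["4"]:
            wins += 1
    assert wins > reps / 2
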