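"""Benchmark Bayesian analysis models: standard HM, no borrowing, EXNEX.

These are the comparators the proposed commensurate-prior analysis is
evaluated against in the simulation study:

1. standard hierarchical model — fully exchangeable treatment effects
   theta_k | mu, tau ~ N(mu, tau^2), mu ~ N(0, 10^2), tau ~ HN(0.125);
2. no borrowing — fully stratified stand-alone fits with vague priors;
3. EXNEX — each theta_k is exchangeable with prior probability 0.5 and
   otherwise follows its own vague N(0, 10^2) prior.

Covariate coefficients share the same random-effects structure as the
operational model (fixed N(0, 5^2) priors for the stratified fits, where
random effects cannot be estimated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AnalysisConfig, BasketTrialData, ValidationError
from .inference import (
    HalfNormalPrior,
    PosteriorDensity,
    _make_posterior,
    _run_chains,
    _stacked_design,
    fit_subtrial_model,
)

__all__ = ["HMSpec", "EXNEXSpec", "fit_standard_hm", "fit_no_borrowing", "fit_exnex"]


@dataclass(frozen=True)
class HMSpec:
    """Exchangeable hierarchy: theta_k ~ N(mu, tau^2)."""

    mu_prior_mean: float = 0.0
    mu_prior_sd: float = 10.0
    tau_prior: HalfNormalPrior = field(default_factory=lambda: HalfNormalPrior(0.125))


@dataclass(frozen=True)
class EXNEXSpec:
    """EXNEX mixture: exchangeable with probability ``ex_prob``, else NEX."""

    ex_prob: float = 0.5
    ex: HMSpec = field(default_factory=HMSpec)
    nex_prior_mean: float = 0.0
    nex_prior_sd: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ex_prob <= 1.0:
            raise ValidationError("ex_prob must lie in [0, 1]")


def _derive_seeds(config: AnalysisConfig, seed: int | None, n: int):
    root = np.random.SeedSequence(config.mcmc.seed if seed is None else seed)
    return [int(s) for s in root.generate_state(n) % np.uint32(2**31)]


def fit_standard_hm(
    trial: BasketTrialData,
    spec: HMSpec | None = None,
    config: AnalysisConfig | None = None,
    *,
    seed: int | None = None,
    diagnostics: bool = True,
) -> dict[str, PosteriorDensity]:
    """Fully exchangeable hierarchical fit of all subtrials."""
    spec = spec or HMSpec()
    config = config or AnalysisConfig()
    trial.validate()
    XtX_all, Xty_all, X, y, offsets, p = _stacked_design(trial.subtrials)
    th, _, _, _ = _run_chains(
        XtX_all,
        Xty_all,
        X,
        y,
        offsets,
        config,
        theta_mode=1,
        mu_mean0=spec.mu_prior_mean,
        mu_var0=spec.mu_prior_sd**2,
        tau_scale=spec.tau_prior.scale,
        seed=seed,
    )
    return {
        s.label: _make_posterior(th[:, :, k], diagnostics, s.label)
        for k, s in enumerate(trial.subtrials)
    }


def fit_no_borrowing(
    trial: BasketTrialData,
    config: AnalysisConfig | None = None,
    *,
    seed: int | None = None,
    diagnostics: bool = True,
) -> dict[str, PosteriorDensity]:
    """Independent stand-alone fits: deleting other subtrials changes nothing."""
    config = config or AnalysisConfig()
    trial.validate(min_subtrials=1)
    seeds = _derive_seeds(config, seed, trial.K)
    return {
        s.label: fit_subtrial_model(
            s,
            (config.theta_prior_mean, config.theta_prior_sd),
            config,
            seed=seeds[k],
            diagnostics=diagnostics,
        )
        for k, s in enumerate(trial.subtrials)
    }


def fit_exnex(
    trial: BasketTrialData,
    spec: EXNEXSpec | None = None,
    config: AnalysisConfig | None = None,
    *,
    seed: int | None = None,
    diagnostics: bool = True,
) -> dict[str, PosteriorDensity]:
    """EXNEX mixture fit with latent per-subtrial exchangeability indicators.

    Each returned posterior carries ``info['p_ex']``, the posterior
    probability that the subtrial is exchangeable (P(NEX) = 1 - P(EX)).
    """
    spec = spec or EXNEXSpec()
    config = config or AnalysisConfig()
    trial.validate()
    XtX_all, Xty_all, X, y, offsets, p = _stacked_design(trial.subtrials)
    th, _, ex, _ = _run_chains(
        XtX_all,
        Xty_all,
        X,
        y,
        offsets,
        config,
        theta_mode=2,
        tpm=np.full(trial.K, spec.nex_prior_mean),
        tpv=np.full(trial.K, spec.nex_prior_sd**2),
        ex_prob=np.full(trial.K, spec.ex_prob),
        mu_mean0=spec.ex.mu_prior_mean,
        mu_var0=spec.ex.mu_prior_sd**2,
        tau_scale=spec.ex.tau_prior.scale,
        seed=seed,
    )
    return {
        s.label: _make_posterior(
            th[:, :, k],
            diagnostics,
            s.label,
            extra={"p_ex": float(ex[:, :, k].mean())},
        )
        for k, s in enumerate(trial.subtrials)
    }
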