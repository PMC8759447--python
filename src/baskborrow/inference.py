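"""Bayesian linear-regression machinery for subtrial treatment effects.

Produces the operational posterior pi_k(theta_k | x_k) for each subtrial:
the posterior of the treatment effect under a vague N(0, 10^2) prior, which
is the reference representation of the information a subtrial carries.
Fits are MCMC-based (see :mod:`baskborrow._gibbs`); results are returned as
:class:`PosteriorDensity` objects holding the draws, moment summaries, a
density evaluator and convergence diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from ._gibbs import gibbs_kernel
from .data import AnalysisConfig, BasketTrialData, SubtrialData, ValidationError

__all__ = [
    "HalfNormalPrior",
    "half_normal_quantile",
    "PosteriorDensity",
    "ConvergenceWarning",
    "fit_linear_model",
    "fit_subtrial_model",
    "fit_joint_operational_model",
    "split_rhat",
    "effective_sample_size",
]

RHAT_LIMIT = 1.05
ESS_LIMIT = 400.0


class ConvergenceWarning(UserWarning):
    """Emitted when split-Rhat or effective sample size look poor."""


@dataclass(frozen=True)
class HalfNormalPrior:
    """HN(scale): a N(0, scale^2) distribution truncated to (0, inf)."""

    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("half-normal scale must be positive")

    def quantile(self, p: float) -> float:
        if not 0 < p < 1:
            raise ValueError(f"probability must lie in (0, 1), got {p}")
        return self.scale * stats.norm.ppf((1.0 + p) / 2.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(
            x >= 0, 2.0 / self.scale * stats.norm.pdf(x / self.scale), 0.0
        )
        return out


def half_normal_quantile(prior: HalfNormalPrior, p: float) -> float:
    """Quantile of HN(z): z * Phi^{-1}((1 + p) / 2)."""
    return prior.quantile(p)


# ---------------------------------------------------------------------------
# convergence diagnostics


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split-Rhat potential scale reduction factor.

    Parameters
    ----------
    chain_draws : array (chains, draws)
    """
    c = np.asarray(chain_draws, dtype=float)
    n = c.shape[1] // 2
    halves = np.concatenate([c[:, :n], c[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    B = n * means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def effective_sample_size(chain_draws: np.ndarray) -> float:
    """Effective sample size via Geyer's initial monotone sequence."""
    c = np.asarray(chain_draws, dtype=float)
    m, n = c.shape
    if n < 4:
        return float(m * n)
    means = c.mean(axis=1, keepdims=True)
    centered = c - means
    W = c.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B_over_n
    if var_plus <= 0:
        return float(m * n)
    # chain-averaged autocovariances via FFT
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive and monotone non-increasing
    tau = -1.0 + 2.0 * rho[0]
    prev = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += 2.0 * pair
        prev = pair
        t += 2
    tau = max(tau, 1.0 / (m * n))
    return float(m * n / tau)


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorDensity:
    """A treatment-effect posterior: draws, moments and a density evaluator.

    ``density`` defaults to the normal approximation N(mean, sd^2), which is
    what the discrepancy module consumes; ``use_kde()`` switches to a
    Gaussian-kernel density estimate over the draws.
    """

    draws: np.ndarray
    chain_draws: np.ndarray | None = None
    rhat: float | None = None
    ess: float | None = None
    info: dict = field(default_factory=dict)
    _kde: Callable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float).ravel()
        if self.draws.size < 2:
            raise ValidationError("a posterior needs at least two draws")
        self.mean = float(self.draws.mean())
        self.sd = float(self.draws.std(ddof=1))
        if self.sd <= 0:
            raise ValidationError("degenerate posterior: sd = 0")

    def density(self, x):
        if self._kde is not None:
            return self._kde(np.atleast_1d(np.asarray(x, dtype=float)))
        return stats.norm.pdf(x, self.mean, self.sd)

    def use_kde(self) -> "PosteriorDensity":
        self._kde = stats.gaussian_kde(self.draws)
        return self

    def exceedance(self, threshold: float) -> float:
        """P(theta > threshold) estimated from the draws."""
        return float(np.mean(self.draws > threshold))

    def quantile(self, p) -> np.ndarray:
        return np.quantile(self.draws, p)

    def summary(self) -> dict:
        lo, med, hi = self.quantile([0.025, 0.5, 0.975])
        out = {
            "mean": self.mean,
            "sd": self.sd,
            "q2.5": float(lo),
            "median": float(med),
            "q97.5": float(hi),
        }
        if self.rhat is not None:
            out["rhat"] = self.rhat
        if self.ess is not None:
            out["ess"] = self.ess
        return out


# ---------------------------------------------------------------------------
# model fitting


def _chain_seeds(seed: int, chains: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(chains) % np.uint32(2**31)


def _run_chains(
    XtX_all,
    Xty_all,
    X,
    y,
    offsets,
    config: AnalysisConfig,
    *,
    theta_mode: int = 0,
    tpm=None,
    tpv=None,
    ex_prob=None,
    mu_mean0: float = 0.0,
    mu_var0: float = 100.0,
    tau_scale: float = 0.125,
    gamma_random: bool | None = None,
    gamma_fixed_mean=None,
    gamma_fixed_var=None,
    sigma_fixed: float = -1.0,
    seed: int | None = None,
):
    """Run the configured number of chains; stack kept draws per chain."""
    K = XtX_all.shape[0]
    ng = XtX_all.shape[1] - 1
    cov = config.covariate_prior
    if gamma_random is None:
        gamma_random = cov.random_effects and K > 1
    if gamma_fixed_mean is None:
        gamma_fixed_mean = np.full(ng, cov.chi_prior_mean)
    if gamma_fixed_var is None:
        gamma_fixed_var = np.full(ng, cov.chi_prior_sd**2)
    if tpm is None:
        tpm = np.full(K, config.theta_prior_mean)
    if tpv is None:
        tpv = np.full(K, config.theta_prior_sd**2)
    if ex_prob is None:
        ex_prob = np.full(K, 0.5)
    mc = config.mcmc
    seeds = _chain_seeds(mc.seed if seed is None else seed, mc.chains)
    theta_chains, sigma_chains, ex_chains, hyper_chains = [], [], [], []
    for s in seeds:
        th, sg, ex, hy = gibbs_kernel(
            XtX_all,
            Xty_all,
            X,
            y,
            offsets,
            mc.iterations,
            mc.burn_in,
            int(s),
            theta_mode,
            np.asarray(tpm, dtype=float),
            np.asarray(tpv, dtype=float),
            np.asarray(ex_prob, dtype=float),
            mu_mean0,
            mu_var0,
            tau_scale,
            1 if gamma_random else 0,
            cov.chi_prior_mean,
            cov.chi_prior_sd**2,
            cov.epsilon_scale,
            np.asarray(gamma_fixed_mean, dtype=float),
            np.asarray(gamma_fixed_var, dtype=float),
            config.sigma_prior_scale,
            sigma_fixed,
        )
        theta_chains.append(th)
        sigma_chains.append(sg)
        ex_chains.append(ex)
        hyper_chains.append(hy)
    return (
        np.stack(theta_chains),
        np.stack(sigma_chains),
        np.stack(ex_chains),
        np.stack(hyper_chains),
    )


def _make_posterior(theta_chains_k: np.ndarray, diagnostics: bool, label: str, extra=None) -> PosteriorDensity:
    post = PosteriorDensity(
        draws=theta_chains_k.ravel(),
        chain_draws=theta_chains_k,
        info=dict(extra or {}),
    )
    if diagnostics:
        post.rhat = split_rhat(theta_chains_k)
        post.ess = effective_sample_size(theta_chains_k)
        if post.rhat > RHAT_LIMIT or post.ess < ESS_LIMIT:
            post.info["converged"] = False
            warnings.warn(
                f"theta[{label}]: rhat={post.rhat:.3f}, ess={post.ess:.0f}",
                ConvergenceWarning,
                stacklevel=3,
            )
        else:
            post.info["converged"] = True
    return post


def _stacked_design(subtrials):
    Xs, ys = zip(*(s.design() for s in subtrials))
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    offsets = np.zeros(len(Xs) + 1, dtype=np.int64)
    np.cumsum([x.shape[0] for x in Xs], out=offsets[1:])
    p = X.shape[1]
    XtX_all = np.stack([x.T @ x for x in Xs])
    Xty_all = np.stack([x.T @ yy for x, yy in zip(Xs, ys)])
    return XtX_all, Xty_all, X, y, offsets, p


def fit_linear_model(
    X: np.ndarray,
    y: np.ndarray,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    config: AnalysisConfig,
    *,
    sigma_fixed: float | None = None,
    seed: int | None = None,
    diagnostics: bool = True,
    label: str = "0",
) -> PosteriorDensity:
    """Fit one Gaussian regression block with independent normal priors.

    The last column of ``X`` is the parameter whose posterior is returned.
    An empty ``X`` (zero rows) yields prior-only sampling, useful for
    checking that the sampler reproduces its priors.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    XtX = (X.T @ X)[None, :, :]
    Xty = (X.T @ y)[None, :]
    offsets = np.array([0, X.shape[0]], dtype=np.int64)
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    th, _, _, _ = _run_chains(
        XtX,
        Xty,
        X,
        y,
        offsets,
        config,
        theta_mode=0,
        tpm=np.array([prior_mean[-1]]),
        tpv=np.array([prior_var[-1]]),
        gamma_random=False,
        gamma_fixed_mean=prior_mean[:-1],
        gamma_fixed_var=prior_var[:-1],
        sigma_fixed=-1.0 if sigma_fixed is None else float(sigma_fixed),
        seed=seed,
    )
    return _make_posterior(th[:, :, 0], diagnostics, label)


def fit_subtrial_model(
    subtrial: SubtrialData,
    theta_prior: tuple[float, float],
    config: AnalysisConfig,
    *,
    seed: int | None = None,
    diagnostics: bool = True,
) -> PosteriorDensity:
    """Stand-alone posterior for one subtrial's treatment effect.

    ``theta_prior`` is (mean, sd) of the normal prior on theta_k; covariate
    coefficients get fixed N(0, 5^2) priors since random effects cannot be
    estimated from a single subtrial.  This is both the no-borrowing
    analysis and the predictive-prior update when ``theta_prior`` carries
    the marginal predictive prior moments.
    """
    subtrial.validate()
    m, sd = theta_prior
    if sd <= 0:
        raise ValidationError("theta prior sd must be positive")
    X, y = subtrial.design()
    XtX = (X.T @ X)[None, :, :]
    Xty = (X.T @ y)[None, :]
    offsets = np.array([0, X.shape[0]], dtype=np.int64)
    th, _, _, _ = _run_chains(
        XtX,
        Xty,
        X,
        y,
        offsets,
        config,
        theta_mode=0,
        tpm=np.array([m], dtype=float),
        tpv=np.array([sd**2], dtype=float),
        gamma_random=False,
        seed=seed,
    )
    return _make_posterior(th[:, :, 0], diagnostics, subtrial.label)


def fit_joint_operational_model(
    trial: BasketTrialData,
    config: AnalysisConfig,
    *,
    seed: int | None = None,
    diagnostics: bool = True,
) -> dict[str, PosteriorDensity]:
    """Operational posteriors for all subtrials from one joint fit.

    Treatment effects keep independent vague N(0, 10^2) priors — no
    information flows between them — while covariate coefficients share the
    random-effects structure gamma_jk ~ N(chi_j, eps_j^2), chi_j ~ N(0, 5^2),
    eps_j ~ HN(1), and the residual sd is common with an HN prior.
    """
    trial.validate(min_subtrials=1)
    XtX_all, Xty_all, X, y, offsets, p = _stacked_design(trial.subtrials)
    th, _, _, _ = _run_chains(
        XtX_all, Xty_all, X, y, offsets, config, theta_mode=0, seed=seed
    )
    return {
        s.label: _make_posterior(th[:, :, k], diagnostics, s.label)
        for k, s in enumerate(trial.subtrials)
    }
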