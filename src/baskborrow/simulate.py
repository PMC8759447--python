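"""Scenario-driven trial simulator, Go/No-go rule and operating characteristics.

The generator emulates a randomized, placebo-controlled basket trial with
K = 6 subtrials of unequal sizes n = (10, 10, 14, 16, 20, 20).  Per
patient, two covariates z1 ~ N(6, 0.2^2) (the baseline measurement of the
endpoint) and z2 ~ N(4, 0.2^2) are drawn independently, treatment is
assigned by block allocation with exactly half of each subtrial on each
arm, and the outcome follows

    y ~ N(5 + 3 z1 + 1.3 z2 + T theta_k, 0.4^2).

Nine named scenarios cover consistent, divergent, mixed-null and
global-null configurations of the true effects theta_k.

Operating characteristics over M replicates report, per subtrial, the bias
and MSE of the posterior mean, the Go rate under P(theta_k > delta_U) >
zeta, and the overall type-I-error analog: the proportion of replicates
with an erroneous Go in at least one truly null (theta_k = 0) subtrial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .borrowing import analyze_proposed
from .comparators import fit_exnex, fit_no_borrowing, fit_standard_hm
from .data import (
    AnalysisConfig,
    BasketTrialData,
    DecisionRule,
    PatientRecord,
    SubtrialData,
    ValidationError,
)
from .inference import PosteriorDensity

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "generate_trial",
    "decide_go_nogo",
    "OCResult",
    "run_operating_characteristics",
    "METHODS",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative truth for one simulation scenario."""

    theta_true: tuple[float, ...]
    n: tuple[int, ...] = (10, 10, 14, 16, 20, 20)
    gamma_true: tuple[float, float, float] = (5.0, 3.0, 1.3)
    sigma: float = 0.4
    covariate_means: tuple[float, ...] = (6.0, 4.0)
    covariate_sd: float = 0.2
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.theta_true) != len(self.n):
            raise ValidationError("theta_true and n must have equal length")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if any(nk % 2 != 0 or nk < 2 for nk in self.n):
            raise ValidationError("each n_k must be even (block halves) and >= 2")

    @property
    def K(self) -> int:
        return len(self.theta_true)

    @property
    def null_subtrials(self) -> tuple[int, ...]:
        """Indices of truly null subtrials (theta_k = 0)."""
        return tuple(k for k, t in enumerate(self.theta_true) if t == 0.0)


def _scn(name, *theta):
    return ScenarioSpec(theta_true=theta, name=name)


#: The nine study scenarios: varying effect sizes and heterogeneity, with
#: 7 and 8 mixed-null and 9 the global null.
SCENARIOS: dict[int, ScenarioSpec] = {
    1: _scn("heterogeneous", 0.49, 0.67, 0.54, 0.43, 0.79, 0.35),
    2: _scn("divergent", 0.35, 0.37, 0.80, 1.30, 1.38, 0.40),
    3: _scn("two-cluster", 0.29, 0.77, 0.68, 0.75, 0.33, 0.30),
    4: _scn("one-low", 0.59, 1.17, 1.02, 0.95, 0.13, 0.75),
    5: _scn("consistent-moderate", *(0.45,) * 6),
    6: _scn("consistent-low", *(0.30,) * 6),
    7: _scn("mixed-null-a", 0.0, 0.0, 0.0, 0.0, 0.37, 0.37),
    8: _scn("mixed-null-b", 0.33, 0.0, 0.82, 0.90, 0.0, 0.83),
    9: _scn("global-null", *(0.0,) * 6),
}


def generate_trial(scenario: ScenarioSpec, seed: int) -> BasketTrialData:
    """Simulate one basket trial under the scenario's generative truth."""
    rng = np.random.default_rng(seed)
    g0, g1, g2 = scenario.gamma_true
    m1, m2 = scenario.covariate_means
    subtrials = []
    for k, (nk, theta) in enumerate(zip(scenario.n, scenario.theta_true)):
        z1 = rng.normal(m1, scenario.covariate_sd, nk)
        z2 = rng.normal(m2, scenario.covariate_sd, nk)
        T = np.zeros(nk, dtype=int)
        T[rng.permutation(nk)[: nk // 2]] = 1
        eta = g0 + g1 * z1 + g2 * z2 + T * theta
        y = rng.normal(eta, scenario.sigma)
        recs = [
            PatientRecord(treatment=int(T[i]), covariates=(z1[i], z2[i]), outcome=y[i])
            for i in range(nk)
        ]
        subtrials.append(SubtrialData(label=str(k + 1), records=recs))
    return BasketTrialData(subtrials)


def decide_go_nogo(
    posterior: PosteriorDensity, rule: DecisionRule
) -> tuple[bool, float]:
    """Go iff P(theta > delta_U) > zeta; returns (decision, exceedance)."""
    prob = posterior.exceedance(rule.delta_U)
    return prob > rule.zeta, prob


def _fit_proposed(trial, config, seed):
    return analyze_proposed(trial, config, seed=seed, diagnostics=False).posteriors


METHODS = {
    "proposed": _fit_proposed,
    "hm": lambda trial, config, seed: fit_standard_hm(
        trial, config=config, seed=seed, diagnostics=False
    ),
    "exnex": lambda trial, config, seed: fit_exnex(
        trial, config=config, seed=seed, diagnostics=False
    ),
    "none": lambda trial, config, seed: fit_no_borrowing(
        trial, config=config, seed=seed, diagnostics=False
    ),
}


@dataclass
class OCResult:
    """Per-subtrial and overall operating characteristics over M replicates."""

    scenario: ScenarioSpec
    method: str
    reps: int
    labels: list[str]
    bias: np.ndarray
    mse: np.ndarray
    rejection_rate: np.ndarray
    rejection_mc_se: np.ndarray
    overall_error: float | None
    overall_mc_se: float | None
    n_failed: int = 0
    posterior_means: np.ndarray | None = field(default=None, repr=False)
    go_matrix: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "scenario": self.scenario.name,
            "method": self.method,
            "reps": self.reps,
            "n_failed": self.n_failed,
            "per_subtrial": [
                {
                    "subtrial": lab,
                    "theta_true": self.scenario.theta_true[k],
                    "bias": float(self.bias[k]),
                    "mse": float(self.mse[k]),
                    "rejection_rate": float(self.rejection_rate[k]),
                    "mc_se": float(self.rejection_mc_se[k]),
                }
                for k, lab in enumerate(self.labels)
            ],
        }
        if self.overall_error is not None:
            out["overall_error"] = self.overall_error
            out["overall_mc_se"] = self.overall_mc_se
        return out


def replicate_seeds(master_seed: int, m: int) -> tuple[int, int]:
    """Independent (data, mcmc) child seeds for replicate m.

    Derived from (master seed, replicate index) so that partial runs are
    reproducible and method comparisons under the same master seed are
    paired on identical data streams.
    """
    data_s, mcmc_s = np.random.SeedSequence((master_seed, m)).generate_state(
        2
    ) % np.uint32(2**31)
    return int(data_s), int(mcmc_s)


def run_operating_characteristics(
    scenario: ScenarioSpec,
    method: str,
    rule: DecisionRule,
    reps: int,
    seed: int,
    config: AnalysisConfig | None = None,
    *,
    max_failure_rate: float = 0.05,
    keep_replicates: bool = False,
) -> OCResult:
    """Monte-Carlo operating characteristics of one analysis model.

    Per replicate: simulate a trial, fit, record the posterior mean of each
    theta_k and the Go decision.  Bias and MSE average the posterior-mean
    errors; the overall error is the proportion of replicates with >= 1
    erroneous Go among truly null subtrials (None if the scenario has no
    null subtrial).
    """
    if reps < 1:
        raise ValidationError("reps must be at least 1")
    fitter = METHODS[method] if isinstance(method, str) else method
    config = config or AnalysisConfig.reduced()
    K = scenario.K
    means = np.full((reps, K), np.nan)
    go = np.zeros((reps, K), dtype=bool)
    ok = np.zeros(reps, dtype=bool)
    n_failed = 0
    for m in range(reps):
        data_seed, mcmc_seed = replicate_seeds(seed, m)
        trial = generate_trial(scenario, data_seed)
        try:
            posteriors = fitter(trial, config, mcmc_seed)
        except Exception:
            n_failed += 1
            if n_failed > max_failure_rate * reps:
                raise RuntimeError(
                    f"{n_failed} fit failures in {m + 1} replicates"
                )
            continue
        ok[m] = True
        for k, s in enumerate(trial.subtrials):
            post = posteriors[s.label]
            means[m, k] = post.mean
            go[m, k], _ = decide_go_nogo(post, rule)

    used = int(ok.sum())
    mu = means[ok]
    theta = np.asarray(scenario.theta_true)
    bias = mu.mean(axis=0) - theta
    mse = ((mu - theta) ** 2).mean(axis=0)
    rej = go[ok].mean(axis=0)
    rej_se = np.sqrt(rej * (1 - rej) / used)
    nulls = scenario.null_subtrials
    if nulls:
        any_err = go[ok][:, list(nulls)].any(axis=1)
        overall = float(any_err.mean())
        overall_se = float(np.sqrt(overall * (1 - overall) / used))
    else:
        overall = overall_se = None
    return OCResult(
        scenario=scenario,
        method=method if isinstance(method, str) else getattr(method, "__name__", "custom"),
        reps=used,
        labels=[str(k + 1) for k in range(K)],
        bias=bias,
        mse=mse,
        rejection_rate=rej,
        rejection_mc_se=rej_se,
        overall_error=overall,
        overall_mc_se=overall_se,
        n_failed=n_failed,
        posterior_means=means if keep_replicates else None,
        go_matrix=go if keep_replicates else None,
    )
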