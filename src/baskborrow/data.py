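"""Domain containers for randomized basket-trial data and analysis configuration.

A basket trial evaluates one treatment in K disease-defined patient
subgroups ("subtrials") at once.  Each patient record carries the subtrial
label, a binary treatment indicator (1 = treatment, 0 = placebo), ``q``
baseline covariates and a continuous outcome.  The on-disk exchange format
is a flat CSV with columns ``subtrial,treatment,z1..zq,outcome``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "SubtrialData",
    "BasketTrialData",
    "CovariatePriorSpec",
    "SpikeSlabSpec",
    "DecisionRule",
    "MCMCSettings",
    "AnalysisConfig",
    "read_trial_csv",
    "write_trial_csv",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Raised when trial data violate a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file does not follow the expected schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: treatment arm, covariate vector and continuous outcome."""

    treatment: int
    covariates: tuple[float, ...]
    outcome: float

    def __post_init__(self) -> None:
        if self.treatment not in (0, 1):
            raise ValidationError(
                f"treatment indicator must be 0 or 1, got {self.treatment!r}"
            )


@dataclass
class SubtrialData:
    """All patients recruited to one subtrial, in recruitment order."""

    label: str
    records: list[PatientRecord]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def q(self) -> int:
        return len(self.records[0].covariates) if self.records else 0

    def validate(self, require_both_arms: bool = True) -> None:
        if self.n < 2:
            raise ValidationError(f"subtrial {self.label!r} has n={self.n} < 2")
        q = self.q
        for r in self.records:
            if len(r.covariates) != q:
                raise ValidationError(
                    f"subtrial {self.label!r}: inconsistent covariate length"
                )
        if require_both_arms:
            arms = {r.treatment for r in self.records}
            if arms != {0, 1}:
                raise ValidationError(
                    f"subtrial {self.label!r} must contain both arms, found {arms}"
                )

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix ``[1, z1..zq, T]`` and outcome vector.

        The treatment indicator is the last column, so the treatment effect
        is always the final regression coefficient.
        """
        X = np.empty((self.n, self.q + 2))
        y = np.empty(self.n)
        for i, r in enumerate(self.records):
            X[i, 0] = 1.0
            X[i, 1 : 1 + self.q] = r.covariates
            X[i, -1] = r.treatment
            y[i] = r.outcome
        return X, y


@dataclass
class BasketTrialData:
    """An ordered collection of subtrials sharing one covariate dimension."""

    subtrials: list[SubtrialData]

    @property
    def K(self) -> int:
        return len(self.subtrials)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.subtrials]

    @property
    def q(self) -> int:
        return self.subtrials[0].q if self.subtrials else 0

    def validate(self, min_subtrials: int = 2) -> None:
        if self.K < min_subtrials:
            raise ValidationError(f"need at least {min_subtrials} subtrials, got {self.K}")
        q = self.q
        for s in self.subtrials:
            s.validate()
            if s.q != q:
                raise ValidationError(
                    f"subtrial {s.label!r} has q={s.q}, expected {q}"
                )

    def excluding(self, label: str) -> "BasketTrialData":
        """The complementary trial data with one subtrial removed."""
        return BasketTrialData([s for s in self.subtrials if s.label != label])

    def __getitem__(self, label: str) -> SubtrialData:
        for s in self.subtrials:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        q = self.q
        cov_names = [f"z{j + 1}" for j in range(q)]
        for s in self.subtrials:
            for r in s.records:
                row = {"subtrial": s.label, "treatment": r.treatment}
                row.update(dict(zip(cov_names, r.covariates)))
                row["outcome"] = r.outcome
                rows.append(row)
        return pd.DataFrame(rows, columns=["subtrial", "treatment", *cov_names, "outcome"])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CovariatePriorSpec:
    """Priors for covariate main effects gamma_jk.

    With ``random_effects`` on, gamma_jk ~ N(chi_j, eps_j^2) with
    chi_j ~ N(chi_prior_mean, chi_prior_sd^2) and eps_j ~ HN(epsilon_scale),
    permitting limited sharing of covariate information across subtrials.
    Off, every gamma_jk gets an independent fixed N(0, 5^2) prior (the
    stand-alone / no-borrowing setting).
    """

    chi_prior_mean: float = 0.0
    chi_prior_sd: float = 5.0
    epsilon_scale: float = 1.0
    random_effects: bool = True

    def __post_init__(self) -> None:
        if self.epsilon_scale <= 0:
            raise ValidationError("epsilon_scale must be positive")


@dataclass
class SpikeSlabSpec:
    """Bounds of the spike-and-slab prior on the commensurability precision."""

    B1: float = 0.01
    B2: float = 1.0
    S: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.B1 < self.B2 < self.S):
            raise ValidationError("require 0 <= B1 < B2 < S")


@dataclass
class DecisionRule:
    """Go/No-go rule: Go iff P(theta_k > delta_U) > zeta."""

    delta_U: float = 0.25
    zeta: float = 0.975

    def __post_init__(self) -> None:
        if not 0 < self.zeta < 1:
            raise ValidationError("zeta must lie in (0, 1)")


@dataclass
class MCMCSettings:
    chains: int = 2
    iterations: int = 10_000
    burn_in: int = 3_000
    seed: int = 20200507

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValidationError("require iterations > burn_in >= 0")


@dataclass
class AnalysisConfig:
    """Everything the analysis models need besides the data.

    Defaults follow the simulation-study configuration: vague N(0, 10^2)
    operational prior on each treatment effect, spike-and-slab bounds
    (B1, B2, S) = (0.01, 1, 100), distance-to-weight scale s0 = 0.15, and a
    Go rule P(theta > 0.25) > 0.975.
    """

    theta_prior_mean: float = 0.0
    theta_prior_sd: float = 10.0
    covariate_prior: CovariatePriorSpec = field(default_factory=CovariatePriorSpec)
    spike_slab: SpikeSlabSpec = field(default_factory=SpikeSlabSpec)
    s0: float = 0.15
    decision: DecisionRule = field(default_factory=DecisionRule)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    sigma_prior_scale: float = 2.5
    # "joint": operational posteriors from the joint random-effects fit;
    # "stratified": from fully independent per-subtrial fits.
    operational: str = "joint"
    # "normal": closed-form Hellinger distance on moment-matched normals;
    # "kde": kernel density estimate + quadrature.
    hellinger: str = "normal"

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValidationError("s0 must be positive")
        if self.theta_prior_sd <= 0:
            raise ValidationError("theta_prior_sd must be positive")
        if self.sigma_prior_scale <= 0:
            raise ValidationError("sigma_prior_scale must be positive")
        if self.operational not in ("joint", "stratified"):
            raise ValidationError("operational must be 'joint' or 'stratified'")
        if self.hellinger not in ("normal", "kde"):
            raise ValidationError("hellinger must be 'normal' or 'kde'")

    @classmethod
    def reduced(cls, **kwargs) -> "AnalysisConfig":
        """Short-chain profile (2 x 2000 iterations, 500 burn-in).

        Intended for simulation studies and test suites where tens of
        thousands of model fits are required; posterior summaries at this
        length are accurate to a few thousandths on the outcome scale.
        """
        kwargs.setdefault("mcmc", MCMCSettings(chains=2, iterations=2000, burn_in=500))
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("covariate_prior", CovariatePriorSpec),
            ("spike_slab", SpikeSlabSpec),
            ("decision", DecisionRule),
            ("mcmc", MCMCSettings),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# CSV I/O

_RESERVED = ("subtrial", "treatment", "outcome")


def read_trial_csv(path, covariate_columns: Sequence[str] | None = None) -> BasketTrialData:
    """Read patient-level basket-trial data from CSV.

    Parameters
    ----------
    path : file path
        CSV with columns ``subtrial``, ``treatment``, ``outcome`` plus the
        covariate columns.
    covariate_columns : sequence of str, optional
        Names of the covariate columns.  Default: every non-reserved column,
        in file order.
    """
    df = pd.read_csv(path)
    for col in _RESERVED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c not in _RESERVED]
    else:
        missing = [c for c in covariate_columns if c not in df.columns]
        if missing:
            raise FormatError(f"missing covariate column(s) {missing}")

    bad = ~df["treatment"].isin((0, 1))
    if bad.any():
        raise ValidationError(
            f"non-binary treatment value(s): {df.loc[bad, 'treatment'].unique()[:5]}"
        )

    subtrials = []
    for label, grp in df.groupby("subtrial", sort=False):
        recs = [
            PatientRecord(
                treatment=int(row.treatment),
                covariates=tuple(float(getattr(row, c)) for c in covariate_columns),
                outcome=float(row.outcome),
            )
            for row in grp.itertuples()
        ]
        if not recs:
            raise ValidationError(f"subtrial {label!r} is empty")
        subtrials.append(SubtrialData(label=str(label), records=recs))
    if not subtrials:
        raise ValidationError("file contains no patient records")
    trial = BasketTrialData(subtrials)
    trial.validate(min_subtrials=1)
    return trial


def write_trial_csv(trial: BasketTrialData, path) -> None:
    """Write a basket trial to CSV (full float precision; round-trips)."""
    trial.to_frame().to_csv(path, index=False, float_format="%.17g")
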