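"""Hellinger distance between subtrial posteriors.

The Hellinger distance between two densities p and q,

    d_H(p, q) = sqrt( (1/2) * integral ( sqrt(p) - sqrt(q) )^2 )
             = sqrt( 1 - integral sqrt(p * q) ),

is symmetric, bounded in [0, 1] and invariant under any common monotone
reparameterization of both variables — which makes it a natural probability-
scale measure of how commensurate two subtrials' treatment effects are.
For two normals there is a closed form, used as the default estimator
because linear-model posteriors under vague priors are very nearly normal;
a KDE + quadrature route is available for non-normal evaluators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .data import ValidationError

__all__ = [
    "hellinger_normal",
    "hellinger_numeric",
    "DiscrepancyMatrix",
    "build_discrepancy_matrix",
    "slab_weight",
]


def hellinger_normal(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Closed-form Hellinger distance between N(mean1, sd1^2) and N(mean2, sd2^2)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("normal sds must be positive")
    v = sd1 * sd1 + sd2 * sd2
    bc = np.sqrt(2.0 * sd1 * sd2 / v) * np.exp(-((mean1 - mean2) ** 2) / (4.0 * v))
    return float(np.clip(np.sqrt(max(1.0 - bc, 0.0)), 0.0, 1.0))


def hellinger_numeric(p, q, *, support: tuple[float, float] | None = None) -> float:
    """Hellinger distance by adaptive quadrature of the Bhattacharyya overlap.

    ``p`` and ``q`` expose ``mean``, ``sd`` and a vectorizable ``density``
    callable (e.g. :class:`~baskborrow.inference.PosteriorDensity`).  The
    integral runs over the union of both mean +/- 10 sd ranges unless an
    explicit ``support`` is given.
    """
    if support is None:
        lo = min(p.mean - 10.0 * p.sd, q.mean - 10.0 * q.sd)
        hi = max(p.mean + 10.0 * p.sd, q.mean + 10.0 * q.sd)
    else:
        lo, hi = support

    def integrand(x):
        fp = float(np.squeeze(p.density(x)))
        fq = float(np.squeeze(q.density(x)))
        if not (np.isfinite(fp) and np.isfinite(fq)) or fp < 0 or fq < 0:
            raise ValidationError(f"non-finite or negative density at x={x}")
        return np.sqrt(fp * fq)

    bc, _ = integrate.quad(
        integrand, lo, hi, limit=200, points=[p.mean, q.mean], epsabs=1e-10
    )
    return float(np.clip(np.sqrt(max(1.0 - bc, 0.0)), 0.0, 1.0))


@dataclass
class DiscrepancyMatrix:
    """Symmetric K x K matrix of pairwise Hellinger distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = len(self.labels)
        if self.values.shape != (K, K):
            raise ValidationError("matrix shape must match the label count")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("discrepancy matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("diagonal must be exactly zero")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValidationError("all distances must lie in [0, 1]")

    def distances_to(self, label: str) -> dict[str, float]:
        """Column of pairwise distances from every other subtrial to ``label``."""
        j = self.labels.index(label)
        return {
            lab: float(self.values[i, j])
            for i, lab in enumerate(self.labels)
            if lab != label
        }

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "values": self.values.tolist()}


def build_discrepancy_matrix(posteriors: dict, method: str = "normal") -> DiscrepancyMatrix:
    """Pairwise Hellinger distances between the subtrial posteriors.

    Each unordered pair is computed once and mirrored; the diagonal is
    exactly zero.  ``method='normal'`` uses the closed form on the draw
    mean/sd; ``method='kde'`` integrates kernel density estimates.
    """
    if len(posteriors) < 2:
        raise ValidationError("need at least two posteriors")
    labels = list(posteriors)
    K = len(labels)
    d = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            p, q = posteriors[labels[i]], posteriors[labels[j]]
            if method == "normal":
                dij = hellinger_normal(p.mean, p.sd, q.mean, q.sd)
            elif method == "kde":
                dij = hellinger_numeric(p.use_kde(), q.use_kde())
            else:
                raise ValidationError(f"unknown method {method!r}")
            d[i, j] = d[j, i] = dij
    return DiscrepancyMatrix(labels=labels, values=d)


def slab_weight(d: float) -> float:
    """Slab probability w from a Hellinger distance: the identity w = d.

    A distance of 0 (perfectly consistent subtrials) puts all spike-and-slab
    mass on the spike — full borrowing; a distance of 1 puts it all on the
    slab — the source is discarded.
    """
    if not 0.0 <= d <= 1.0:
        raise ValidationError(f"distance must lie in [0, 1], got {d}")
    return float(d)
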