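"""The borrowing machinery on hand-made posteriors, step by step.

Builds three source posteriors (two mutually consistent, one conflicting),
computes pairwise Hellinger distances, turns them into spike-and-slab slab
probabilities and softmax borrowing weights, and combines the per-source
commensurate predictive priors into one marginal predictive prior (MPP).
Watch how the conflicting source is doubly discounted: its CPP variance is
inflated through the slab and its weight is driven toward zero.
"""

import numpy as np

from baskborrow import (
    PosteriorDensity,
    SpikeSlabPrior,
    combine_mpp,
    hellinger_normal,
    marginal_cpp_moments,
    weights_from_distances,
)

rng = np.random.default_rng(0)
target_mean, target_sd = 0.40, 0.15
sources = {
    "consistent-A": (0.42, 0.15),
    "consistent-B": (0.35, 0.16),
    "conflicting": (1.60, 0.15),
}

print(f"target operational posterior: N({target_mean}, {target_sd}^2)\n")
cpps, dists = [], {}
for name, (m, s) in sources.items():
    d = hellinger_normal(target_mean, target_sd, m, s)
    dists[name] = d
    prior = SpikeSlabPrior(B1=0.01, B2=1.0, S=100.0, w=d)  # slab probability = distance
    post = PosteriorDensity(draws=rng.normal(m, s, 20_000))
    cpp = marginal_cpp_moments(post, prior, label=name)
    cpps.append(cpp)
    print(
        f"{name:13s}: d_H = {d:.3f} -> slab prob w = {d:.3f}; "
        f"CPP ~ N({cpp.lam:.3f}, {cpp.xi2:.3f})"
    )

weights = weights_from_distances(dists, s0=0.15)
print("\nsoftmax weights (s0 = 0.15):")
for name, w in weights.weights.items():
    print(f"  {name:13s}: {w:.4f}")

mpp = combine_mpp(cpps, weights)
print(f"\nmarginal predictive prior: N({mpp.mean:.3f}, {mpp.var:.4f})")
print(
    "\nThe MPP is centred near the consistent sources with a small variance;"
    "\nthe conflicting source's huge CPP variance (~ its slab share of 100)"
    "\nand near-zero weight make it irrelevant to the target's prior."
)
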