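# baskborrow

Bayesian borrowing of information across the subtrials of a randomized,
placebo-controlled **basket trial** with a continuous endpoint.

Basket trials evaluate one treatment in several disease-defined patient
subgroups (subtrials) under a single master protocol. With only 10–20
patients per subtrial, analyzing each subgroup alone is underpowered, while
pooling or assuming full exchangeability risks dragging a genuinely null
subgroup along with its responding neighbours. `baskborrow` implements a
robust middle ground for trial statisticians: information flows to a
subtrial **only from the subtrials whose treatment effects look
commensurate with it**, with the degree of borrowing driven by a
distributional discrepancy measure. Benchmark analyses (standard
hierarchical model, EXNEX, no borrowing) and a scenario-driven simulation
engine for operating characteristics are included.

## The model

Within subtrial $k = 1,\dots,K$, patient outcomes follow a covariate-adjusted
linear model

$$y_{ik} \sim N(\mathbf{z}_{ik}'\gamma_k + T_{ik}\,\theta_k,\ \sigma^2),$$

where $T_{ik}$ is the treatment indicator and $\theta_k$ the subtrial
treatment effect. Each subtrial's information is summarized by its
*operational posterior* $\pi_k(\theta_k \mid x_k)$ under a vague
$N(0, 10^2)$ prior. For a target subtrial $k^\star$, every other subtrial
$k$ contributes a **commensurate predictive prior (CPP)**

$$\theta_{k^\star} \mid \theta_k, \nu \sim N(\theta_k,\ 1/\nu^2),$$

whose precision $\nu$ carries a **spike-and-slab prior**: a point mass at a
spike $S = 100$ (strong borrowing) and a uniform slab on
$[B_1, B_2] = [0.01, 1]$ (discounting), with slab probability set equal to
the **Hellinger distance** $d_{kk^\star} = d_H(\pi_{\theta_k},
\pi_{\theta_{k^\star}})$ between the two operational posteriors
($d_H \in [0,1]$, symmetric, invariant to reparameterization). Marginally
each CPP is summarized as $N(\lambda_k, \xi_k^2)$ with
$\xi_k^2 = \mathrm{Var}(\theta_k) + E[1/\nu^2]$, and the $K-1$ sources are
combined into a **marginal predictive prior**

$$\theta_{k^\star} \mid x_{(-k^\star)} \sim
N\Big(\sum_k p_{kk^\star}\lambda_k,\ \sum_k p_{kk^\star}^2\xi_k^2\Big),
\qquad
p_{kk^\star} = \frac{\exp(-d_{kk^\star}/s_0)}{\sum_k \exp(-d_{kk^\star}/s_0)},$$

with $s_0 = 0.15$ by default. The MPP is updated by the target subtrial's
own likelihood into the robust posterior, and the per-subtrial decision is
**Go** iff $\mathbb{P}(\theta_k > \delta_U) > \zeta$ (defaults
$\delta_U = 0.25$, $\zeta = 0.975$). When all sources are perfectly
consistent ($d = 0$) the method reduces to complete pooling; a conflicting
source is doubly discounted, through its slab-inflated CPP variance and its
vanishing softmax weight.

Posteriors are computed by a blocked Gibbs sampler (exact normal draws for
coefficient blocks, slice updates for half-normal scale parameters) with
ancillarity–sufficiency interweaving for the hierarchical layers, compiled
with numba.

## Worked example

`examples/borrowing_weights.py` walks the borrowing machinery over three
hand-made source posteriors for a target with operational posterior
$N(0.40, 0.15^2)$ — two consistent sources and one conflicting one:

```
consistent-A : d_H = 0.047 -> slab prob w = 0.047; CPP ~ N(0.421, 4.734)
consistent-B : d_H = 0.118 -> slab prob w = 0.118; CPP ~ N(0.350, 11.831)
conflicting  : d_H = 1.000 -> slab prob w = 1.000; CPP ~ N(1.599, 100.006)

softmax weights (s0 = 0.15):
  consistent-A : 0.6154
  consistent-B : 0.3835
  conflicting  : 0.0011

marginal predictive prior: N(0.395, 3.5332)
```

The conflicting source (distance 1) ends up with the full slab — a CPP
variance of ~100, enough to discard it outright — and a weight of 0.001;
the MPP is centred between the consistent sources. In a full trial analysis
(`examples/analyze_basket_trial.py`, a mixed-null scenario where subtrials
2 and 5 are truly null among strong responders) the same mechanism makes
the analysis of subtrial 2 place weight 0.79 on subtrial 5, its fellow
null, and 0.004 on the strongest responder.

`examples/operating_characteristics.py` runs a small Monte-Carlo study of
frequentist operating characteristics (bias, MSE, Go rates, overall
type-I-error analog) under the global null.

The same functionality is exposed on the command line:

```bash
baskborrow simulate --scenario 8 --seed 11 --out trial.csv
baskborrow analyze --data trial.csv --method proposed --out results/
baskborrow oc --scenario 9 --method none --reps 500 --seed 1 --out oc.json
```

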