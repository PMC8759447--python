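# Methods

## Data model and decision rule

A basket trial comprises $K \ge 2$ randomized, placebo-controlled
subtrials with a shared continuous endpoint. Patient $i$ of subtrial $k$
contributes covariates $\mathbf{z}_{ik} \in \mathbb{R}^q$, a treatment
indicator $T_{ik} \in \{0,1\}$ and an outcome

$$y_{ik} \sim N(\gamma_{0k} + \mathbf{z}_{ik}'\boldsymbol\gamma_k +
T_{ik}\theta_k,\ \sigma^2).$$

The estimand is the per-subtrial treatment effect $\theta_k$. The trial
decision per subtrial is Go iff $\mathbb{P}(\theta_k > \delta_U \mid
\text{data}) > \zeta$; defaults $\delta_U = 0.25$ (a clinically required
improvement on the outcome scale) and $\zeta = 0.975$, with $\delta_U =
0.30$ and $\zeta = 0.90$ available in the configuration.

## Priors

- Treatment effects: vague $N(0, 10^2)$ operational priors (independent
  across subtrials), the reference representation of each subtrial's own
  information.
- Covariate coefficients: in joint fits, random effects
  $\gamma_{jk} \sim N(\chi_j, \epsilon_j^2)$ with $\chi_j \sim N(0, 5^2)$
  and $\epsilon_j \sim HN(1)$, permitting limited sharing of covariate
  information; in stratified (single-subtrial) fits, fixed $N(0, 5^2)$
  priors, since random effects cannot be estimated from one subtrial.
  $HN(z)$ denotes $N(0, z^2)$ truncated to $(0,\infty)$; $HN(1)$ has
  median 0.674 and central 95% interval (0.031, 2.241).
- Residual sd: $\sigma \sim HN(2.5)$, weakly informative on the outcome
  scale of the simulated trials (residual sd 0.4); the likelihood
  dominates it at every realistic sample size here.

## The borrowing pipeline

For target subtrial $k^\star$:

1. **Operational posteriors** for all $\theta_k$ come, by default, from
   one joint fit (shared $\sigma$, random-effect covariate layer,
   independent $\theta$ priors); a configuration switch
   (`operational: stratified`) uses fully independent fits instead. Which
   of the two feeds the discrepancy step is genuinely open; the joint fit
   is the default because it matches the fitting machinery used by every
   other analysis in the package.
2. **Discrepancy**: pairwise Hellinger distances
   $d_H(p,q) = \sqrt{1 - \int\sqrt{pq}}$ between operational posteriors,
   organized as a symmetric $K \times K$ matrix with zero diagonal. The
   default estimator is the closed form for two normals applied to the
   draw mean/sd of each posterior — linear-model posteriors under vague
   priors are very nearly normal, and the closed form is deterministic
   given the draws. A KDE + adaptive-quadrature estimator (`hellinger:
   kde`) is provided for non-normal posteriors; the two agree to ~0.01 on
   fitted posteriors. Distances are clipped to $[0,1]$ to guard
   floating-point overshoot at machine precision.
3. **Spike-and-slab commensurability**: each source's CPP precision
   $\nu$ has a point mass at $S = 100$ with probability $1 - w$ and a
   uniform slab on $[B_1, B_2] = [0.01, 1]$ with probability
   $w = d_{kk^\star}$ (the identity mapping; no recalibration curve).
   The marginal CPP moments use the law of total variance:
   $\lambda_k = E[\theta_k]$, $\xi_k^2 = \mathrm{Var}(\theta_k) +
   E[1/\nu^2]$ with $E[1/\nu^2] = w\,\frac{1/B_1 - 1/B_2}{B_2 - B_1} +
   (1-w)/S^2$ — deterministic given the source moments. A Monte-Carlo
   path (explicitly sampling $\nu$ and the predictive draw) is retained
   as a cross-check and agrees within Monte-Carlo error.
4. **Weights**: $p_{kk^\star} = \mathrm{softmax}(-d_{kk^\star}/s_0)$,
   computed shift-invariantly to avoid underflow. $s_0 = 0.15$ by
   default; the sensitivity grid $\{0.15, 0.25, 0.35, 0.45\}$ is a
   one-line configuration change. Equal distances give exactly uniform
   weights; weights are strictly decreasing in distance; $s_0 \to \infty$
   flattens any profile.
5. **Combination and update**: the marginal predictive prior is
   $N(\sum p\lambda, \sum p^2\xi^2)$; the target subtrial's regression is
   then refit with this prior on $\theta_{k^\star}$, covariates keeping
   fixed $N(0,5^2)$ priors (the update re-evaluates the full
   within-subtrial likelihood rather than a $\theta$-only summary;
   whether covariate information should also be shared at this step is
   unstated in the underlying formulation, and fixed priors keep the
   update self-contained).

Limits: all $d = 0$ with common source moments $(\lambda, \xi^2)$ gives an
MPP variance $\xi^2/(K-1)$ and an updated posterior variance $\xi^2/K$ —
complete pooling; $d = 1$ sources are discarded. A source posterior with
zero spread makes the distance undefined and raises an error rather than
silently borrowing in full.

A consequence worth stating plainly: because $E[1/\nu^2] \approx 100w$,
any distance above a few hundredths makes a source's CPP variance large
relative to a subtrial likelihood variance of ~0.05–0.1, so at the sample
sizes studied here the moment-matched MPP is nearly vague unless sources
are almost indistinguishable. The pipeline therefore errs strongly toward
no borrowing at intermediate discrepancies; its gains concentrate in the
near-consistent regime. The robustness tests (outlier-source injection)
and the pooling-limit checks probe the two ends of this spectrum.

## Comparator models

- **Standard hierarchical model**: $\theta_k \sim N(\mu, \tau^2)$,
  $\mu \sim N(0, 10^2)$, $\tau \sim HN(0.125)$ ($HN(0.125)$: median
  0.084, 95% interval (0.004, 0.280) — deliberately tight, favouring
  strong shrinkage).
- **No borrowing**: fully stratified stand-alone fits.
- **EXNEX**: per subtrial, $\theta_k$ is exchangeable (as in the HM) with
  prior probability 0.5 and otherwise follows its own $N(0, 10^2)$; latent
  indicators are sampled by data augmentation and their posterior
  occupancy is reported per subtrial. With exchangeability probability 1
  EXNEX collapses to the HM; with probability 0 it collapses to the joint
  model with independent effects (the covariate layer and residual sd
  remain shared, so it matches the fully stratified analysis only up to
  that structural difference — the NEX component applies to $\theta_k$
  only).

## Sampler

All models run on one blocked Gibbs kernel (numba-compiled):

- coefficient blocks $(\gamma_k, \theta_k)$: exact multivariate-normal
  conditional draws via Cholesky;
- scale parameters ($\sigma$, $\epsilon_j$, $\tau$) with half-normal
  priors: univariate slice sampling (stepping-out + shrinkage, step width
  keyed to both the current value and the prior scale);
- EXNEX indicators: exact Bernoulli conditionals;
- **ancillarity–sufficiency interweaving** for both hierarchies: after
  the standard updates, $\chi_j$ and $\epsilon_j$ (and $\mu$, $\tau$ in
  exchangeable models) are re-drawn in the ancillary parameterization
  $\gamma_{jk} = \chi_j + \epsilon_j u_{jk}$, where they appear as direct
  regression coefficients (positive coefficients drawn from truncated
  normals). This removes the funnel that otherwise appears when group
  effects are nearly homogeneous — without it, effective sample sizes for
  $\theta_k$ drop below 50 per 3000 draws in joint fits; with it they sit
  near the draw count.

Defaults follow the long-run profile (2 chains × 10,000 iterations, 3,000
burn-in). The test suite and the simulation engine use a reduced profile
(2 × 2,000, 500 burn-in), at which posterior means carry Monte-Carlo error
of a few thousandths on this outcome scale. Convergence is gated
non-fatally at split-$\hat R \le 1.05$ and ESS $\ge 400$ (both computed
in-package and cross-checked against arviz); the simulation engine skips
diagnostics for speed. Sampler correctness is established by a
known-$\sigma$ conjugate oracle, prior-only reproduction of the $N(0,10^2)$,
$HN(2.5)$ and $HN(0.125)$ priors, and the exact $\xi^2/K$ pooling identity
on the known-$\sigma$ pathway (with $\sigma$ re-estimated, $\sigma$–$\theta$
coupling moves the updated variance by ~5–10%, which is why that check
fixes $\sigma$).

## Synthetic trials and operating characteristics

The generator emulates a six-subtrial phase II basket trial: sample sizes
$n = (10, 10, 14, 16, 20, 20)$ split exactly half-and-half between arms by
block allocation; covariates $z_1 \sim N(6, 0.2^2)$ (baseline measurement
of the endpoint) and $z_2 \sim N(4, 0.2^2)$, independent; outcomes from
$\gamma = (5, 3, 1.3)$, $\sigma = 0.4$. Nine named scenarios span
consistent, divergent, mixed-null and global-null effect configurations.
What the generator does **not** emulate: covariate–outcome confounding
beyond the linear main effects, correlated or skewed covariates,
non-Gaussian residuals, dropout, or unequal randomization — so passing
tests demonstrate correctness of the machinery under the stated generative
model, not robustness to real-data violations of it. The near-collinearity
of the design (intercept vs. tightly concentrated covariates) is
intentional and stress-tests the sampler's hierarchical layer.

Operating characteristics over $M$ replicates report per subtrial the bias
and MSE of the posterior mean ($\mathrm{MSE} - \mathrm{bias}^2$ equals the
empirical variance to $10^{-10}$, a tested identity), Go rates with
binomial standard errors, and the overall type-I-error analog: the share
of replicates with at least one erroneous Go among subtrials whose true
effect is exactly zero (low-but-nonzero effects count toward power, not
error). Replicate $m$ derives independent data and MCMC seeds from the
master seed, so different analysis methods under one master seed see
identical data streams and comparisons are paired. Fit failures are
counted and the run aborts beyond a 5% failure rate.

The acceptance script uses $M = 2000$ replicates for the no-borrowing
global-null rate and $M = 1000$ for the other three rates, with the
reduced MCMC profile; at these sizes an overall rate near 0.005–0.03
carries a binomial standard error of roughly 0.002–0.005, which is the
dominant uncertainty in any single run. The suite's simulation-based
checks use 200–1000 replicates for the same reason.

## Known limitations

- The moment-matched normal MPP understates the information of the
  underlying spike-and-slab mixture at intermediate distances (see the
  pipeline note above); a fully mixture-based update inside MCMC would
  borrow more aggressively but is a different estimator than the one this
  package specifies.
- Continuous endpoints only; no binary/GLM endpoints, interim analyses,
  dose groups, multiple endpoints or unequal randomization.
- Hellinger distances are computed between *approximations* of the
  operational posteriors; with very small subtrials the normal
  approximation (or KDE) error propagates into the slab probabilities.
- The EXNEX NEX component covers the treatment effect only; covariate
  coefficients always share the random-effects layer in joint fits.
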