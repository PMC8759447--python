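"""Numba-compiled Gibbs samplers for the basket-trial regression models.

One kernel covers every analysis model in the package.  Within subtrial k
the likelihood is a Gaussian linear regression

    y_ik ~ N(gamma_0k + z_ik' gamma_k + T_ik theta_k, sigma^2)

with the design laid out as ``[1, z1..zq, T]`` so the treatment effect is
always the last coefficient.  Coefficient blocks are drawn from their exact
multivariate-normal conditionals; scale parameters (residual sd, random-
effect sds, hierarchical tau) carry half-normal priors and are updated by
univariate slice sampling, which leaves the correct invariant distribution
without any tuning.

``theta_mode`` selects the prior structure on the treatment effects:
  0 - independent N(tpm[k], tpv[k]) priors (stand-alone / no borrowing,
      and the predictive-prior update where tpm/tpv hold the MPP moments),
  1 - fully exchangeable hierarchical model theta_k ~ N(mu, tau^2),
  2 - EXNEX mixture with latent per-subtrial exchangeability indicators.
"""

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=True)
def _logp_scale(s, n, ssr, z):
    # log conditional of a scale parameter s > 0 appearing in n Gaussian
    # terms with residual sum of squares ssr, under a HN(z) prior
    return -n * np.log(s) - ssr / (2.0 * s * s) - (s * s) / (2.0 * z * z)


@njit(cache=True)
def _slice_scale(x0, n, ssr, z):
    """One slice-sampling update (stepping out + shrinkage) of a scale."""
    y0 = _logp_scale(x0, n, ssr, z) - (-np.log(np.random.random()))
    # step width keyed to both the current value and the prior scale, so
    # the interval can escape the neighbourhood of zero in prior-like cases
    w = 0.5 * x0 + 0.25 * z
    L = x0 - w * np.random.random()
    if L < _TINY:
        L = _TINY
    R = L + w
    for _ in range(128):
        if L <= _TINY or _logp_scale(L, n, ssr, z) <= y0:
            break
        L -= w
        if L < _TINY:
            L = _TINY
            break
    for _ in range(128):
        if _logp_scale(R, n, ssr, z) <= y0:
            break
        R += w
    for _ in range(128):
        x1 = L + (R - L) * np.random.random()
        if _logp_scale(x1, n, ssr, z) >= y0:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


@njit(cache=True)
def _trunc_normal_pos(m, sd):
    """Draw from N(m, sd^2) truncated to (0, inf).

    Naive rejection near the bulk; Robert's exponential-proposal rejection
    when the positive region is far in the tail.
    """
    alpha = -m / sd
    if alpha < 3.0:
        for _ in range(1000):
            x = m + sd * np.random.normal()
            if x > 0.0:
                return x
    a = (alpha + np.sqrt(alpha * alpha + 4.0)) / 2.0
    for _ in range(1000):
        z = alpha - np.log(np.random.random()) / a
        if np.random.random() <= np.exp(-(z - a) * (z - a) / 2.0):
            return m + sd * z
    return m + sd * max(alpha, 0.0) + _TINY


@njit(cache=True)
def _draw_mvn_prec(P, rhs):
    """Draw from N(P^{-1} rhs, P^{-1}) for a small SPD precision matrix."""
    p = P.shape[0]
    L = np.linalg.cholesky(P)
    v = np.empty(p)
    for i in range(p):
        s = rhs[i]
        for j in range(i):
            s -= L[i, j] * v[j]
        v[i] = s / L[i, i]
    m = np.empty(p)
    u = np.empty(p)
    z = np.empty(p)
    for i in range(p):
        z[i] = np.random.normal()
    for i in range(p - 1, -1, -1):
        s1 = v[i]
        s2 = z[i]
        for j in range(i + 1, p):
            s1 -= L[j, i] * m[j]
            s2 -= L[j, i] * u[j]
        m[i] = s1 / L[i, i]
        u[i] = s2 / L[i, i]
    return m + u


@njit(cache=True)
def _draw_beta(XtX, Xty, sigma2, pm, pv):
    """Draw the coefficient block from its exact normal conditional.

    Posterior precision A = X'X / sigma^2 + diag(1/pv); the draw is
    A^{-1} b + chol(A)^{-T} z with b = X'y / sigma^2 + pm / pv.
    """
    p = XtX.shape[0]
    A = XtX / sigma2
    b = Xty / sigma2
    for j in range(p):
        A[j, j] += 1.0 / pv[j]
        b[j] += pm[j] / pv[j]
    return _draw_mvn_prec(A, b)


@njit(cache=True)
def gibbs_kernel(
    XtX_all,
    Xty_all,
    X,
    y,
    offsets,
    n_iter,
    burn,
    seed,
    theta_mode,
    tpm,
    tpv,
    ex_prob,
    mu_mean0,
    mu_var0,
    tau_scale,
    gamma_random,
    chi_mean0,
    chi_var0,
    eps_scale,
    gm0,
    gv0,
    sigma_scale,
    sigma_fixed,
):
    """Run one chain; return kept draws of (theta, sigma, EX indicators).

    ``sigma_fixed > 0`` freezes the residual sd (known-sigma oracle tests);
    an empty data block (offsets all zero) yields prior-only sampling.
    """
    np.random.seed(seed)
    K = XtX_all.shape[0]
    p = XtX_all.shape[1]
    ng = p - 1  # intercept + covariate coefficients
    beta = np.zeros((K, p))
    chi = np.full(ng, chi_mean0)
    eps = np.full(ng, 0.3 * eps_scale + 0.05)
    mu = mu_mean0
    tau = 0.3 * tau_scale + 0.01
    sigma = sigma_fixed if sigma_fixed > 0.0 else 1.0
    ex = np.ones(K, np.int64)
    n_keep = n_iter - burn
    theta_out = np.empty((n_keep, K))
    sigma_out = np.empty(n_keep)
    ex_out = np.empty((n_keep, K))
    hyper_out = np.empty((n_keep, 2))  # (mu, tau)
    pm = np.empty(p)
    pv = np.empty(p)

    for it in range(n_iter):
        sigma2 = sigma * sigma
        # --- coefficient blocks, one subtrial at a time
        for k in range(K):
            for j in range(ng):
                if gamma_random == 1:
                    pm[j] = chi[j]
                    pv[j] = eps[j] * eps[j] + _TINY
                else:
                    pm[j] = gm0[j]
                    pv[j] = gv0[j]
            if theta_mode == 0 or (theta_mode == 2 and ex[k] == 0):
                pm[p - 1] = tpm[k]
                pv[p - 1] = tpv[k]
            else:
                pm[p - 1] = mu
                pv[p - 1] = tau * tau + _TINY
            beta[k] = _draw_beta(XtX_all[k], Xty_all[k], sigma2, pm, pv)

        # --- EXNEX latent indicators
        if theta_mode == 2:
            for k in range(K):
                th = beta[k, p - 1]
                t2 = tau * tau + _TINY
                le = (
                    np.log(ex_prob[k])
                    - 0.5 * np.log(t2)
                    - (th - mu) * (th - mu) / (2.0 * t2)
                )
                ln = (
                    np.log(1.0 - ex_prob[k])
                    - 0.5 * np.log(tpv[k])
                    - (th - tpm[k]) * (th - tpm[k]) / (2.0 * tpv[k])
                )
                if np.isinf(le) and le < 0:
                    ex[k] = 0
                elif np.isinf(ln) and ln < 0:
                    ex[k] = 1
                else:
                    p_ex = 1.0 / (1.0 + np.exp(ln - le))
                    ex[k] = 1 if np.random.random() < p_ex else 0

        # --- hierarchical location and scale for the exchangeable block
        if theta_mode >= 1:
            t2 = tau * tau + _TINY
            s = 0.0
            cnt = 0
            for k in range(K):
                if theta_mode == 1 or ex[k] == 1:
                    s += beta[k, p - 1]
                    cnt += 1
            prec = cnt / t2 + 1.0 / mu_var0
            mean = (s / t2 + mu_mean0 / mu_var0) / prec
            mu = mean + np.random.normal() / np.sqrt(prec)
            ssr_t = 0.0
            for k in range(K):
                if theta_mode == 1 or ex[k] == 1:
                    d = beta[k, p - 1] - mu
                    ssr_t += d * d
            tau = _slice_scale(tau, cnt, ssr_t, tau_scale)

            # interweaving (ancillary parameterization) for the theta
            # hierarchy: theta_k = mu + tau * t_k with t_k held fixed, so
            # mu and tau are updated directly against the likelihood.
            # Breaks the funnel when tau is small.
            if cnt > 0:
                tt = np.zeros(K)
                for k in range(K):
                    if theta_mode == 1 or ex[k] == 1:
                        tt[k] = (beta[k, p - 1] - mu) / max(tau, 1e-10)
                # mu as a shared coefficient on the treatment column
                prec_mu = 1.0 / mu_var0
                rhs_mu = mu_mean0 / mu_var0
                for k in range(K):
                    if theta_mode == 1 or ex[k] == 1:
                        res = Xty_all[k, p - 1]
                        for j in range(p):
                            cj = beta[k, j]
                            if j == p - 1:
                                cj = tau * tt[k]
                            res -= XtX_all[k, p - 1, j] * cj
                        rhs_mu += res / sigma2
                        prec_mu += XtX_all[k, p - 1, p - 1] / sigma2
                mu = rhs_mu / prec_mu + np.random.normal() / np.sqrt(prec_mu)
                # tau as a positive coefficient on t_k * T_ik
                ell = 1.0 / (tau_scale * tau_scale)
                rhs_tau = 0.0
                for k in range(K):
                    if theta_mode == 1 or ex[k] == 1:
                        res = Xty_all[k, p - 1]
                        for j in range(p):
                            cj = beta[k, j]
                            if j == p - 1:
                                cj = mu
                            res -= XtX_all[k, p - 1, j] * cj
                        rhs_tau += tt[k] * res / sigma2
                        ell += tt[k] * tt[k] * XtX_all[k, p - 1, p - 1] / sigma2
                tau = _trunc_normal_pos(rhs_tau / ell, 1.0 / np.sqrt(ell))
                for k in range(K):
                    if theta_mode == 1 or ex[k] == 1:
                        beta[k, p - 1] = mu + tau * tt[k]

        # --- random-effect hyperparameters for covariate coefficients
        if gamma_random == 1:
            for j in range(ng):
                e2 = eps[j] * eps[j] + _TINY
                prec = K / e2 + 1.0 / chi_var0
                s = 0.0
                for k in range(K):
                    s += beta[k, j]
                mean = (s / e2 + chi_mean0 / chi_var0) / prec
                chi[j] = mean + np.random.normal() / np.sqrt(prec)
                ssr_g = 0.0
                for k in range(K):
                    d = beta[k, j] - chi[j]
                    ssr_g += d * d
                eps[j] = _slice_scale(eps[j], K, ssr_g, eps_scale)

            # interweaving for the covariate hierarchy: gamma_jk =
            # chi_j + eps_j * u_jk with u held fixed; chi becomes a vector
            # of shared regression coefficients and each eps_j a positive
            # coefficient, both updated against the likelihood directly.
            uu = np.zeros((ng, K))
            for j in range(ng):
                ej = max(eps[j], 1e-10)
                for k in range(K):
                    uu[j, k] = (beta[k, j] - chi[j]) / ej
            P = np.zeros((ng, ng))
            rhs = np.zeros(ng)
            for j in range(ng):
                P[j, j] = 1.0 / chi_var0
                rhs[j] = chi_mean0 / chi_var0
            for k in range(K):
                for j in range(ng):
                    res = Xty_all[k, j]
                    for j2 in range(p):
                        cj = eps[j2] * uu[j2, k] if j2 < ng else beta[k, j2]
                        res -= XtX_all[k, j, j2] * cj
                    rhs[j] += res / sigma2
                    for j2 in range(ng):
                        P[j, j2] += XtX_all[k, j, j2] / sigma2
            chi = _draw_mvn_prec(P, rhs)
            for k in range(K):
                for j in range(ng):
                    beta[k, j] = chi[j] + eps[j] * uu[j, k]
            for j in range(ng):
                ell = 1.0 / (eps_scale * eps_scale)
                rhs_e = 0.0
                for k in range(K):
                    res = Xty_all[k, j]
                    for j2 in range(p):
                        cj = chi[j] if j2 == j else beta[k, j2]
                        res -= XtX_all[k, j, j2] * cj
                    rhs_e += uu[j, k] * res / sigma2
                    ell += uu[j, k] * uu[j, k] * XtX_all[k, j, j] / sigma2
                eps[j] = _trunc_normal_pos(rhs_e / ell, 1.0 / np.sqrt(ell))
                for k in range(K):
                    beta[k, j] = chi[j] + eps[j] * uu[j, k]

        # --- residual sd
        if sigma_fixed <= 0.0:
            ssr = 0.0
            for k in range(K):
                for i in range(offsets[k], offsets[k + 1]):
                    r = y[i]
                    for j in range(p):
                        r -= X[i, j] * beta[k, j]
                    ssr += r * r
            sigma = _slice_scale(sigma, offsets[K], ssr, sigma_scale)

        if it >= burn:
            t = it - burn
            for k in range(K):
                theta_out[t, k] = beta[k, p - 1]
                ex_out[t, k] = ex[k]
            sigma_out[t] = sigma
            hyper_out[t, 0] = mu
            hyper_out[t, 1] = tau

    return theta_out, sigma_out, ex_out, hyper_out
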