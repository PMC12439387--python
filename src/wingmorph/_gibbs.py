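"""Numba kernels: exact Polya-Gamma sampling and the blocked Gibbs sampler.

The binary logit-liability animal model is sampled by Polya-Gamma data
augmentation (Polson, Scott & Windle 2013): conditional on auxiliary
variables omega_i ~ PG(1, eta_i), the likelihood in the linear predictor is
Gaussian, so fixed effects, cage effects, the latent unit-variance residual
and the (bivariate) breeding values all have conjugate normal updates.
PG(1, z) variates are drawn by the exact Devroye-type alternating-series
rejection sampler (no truncation approximation).

Variance components use the Huang & Wand (2013) hierarchical prior, which
yields exact half-Student-t(nu) marginals on the standard deviations (nu = 3
here) while keeping inverse-gamma / inverse-Wishart conditionals.

Breeding values are updated single-site (bivariate 2x2 normals) against the
sparse pedigree precision A^-1 supplied in CSR form; all updates run inside
one jitted kernel so a full chain is a single compiled call.
"""

import math

import numpy as np
from numba import njit

_TRUNC = 0.64
_HALF_T_NU = 3.0


# ---------------------------------------------------------------------------
# Polya-Gamma PG(1, z) — Devroye alternating-series sampler
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss(t, z):
    """CDF at t of an inverse-Gaussian(mu=1/z, lambda=1); z >= 0."""
    rt = 1.0 / math.sqrt(t)
    a = _norm_cdf(rt * (t * z - 1.0))
    # guard the exp(2z) * Phi(-...) product against overflow for large z:
    # log Phi(-x) ~ -x^2/2 dominates, so compute in log space
    x = rt * (t * z + 1.0)
    phi = _norm_cdf(-x)
    if phi <= 0.0:
        b = 0.0
    else:
        b = math.exp(2.0 * z + math.log(phi))
    return a + b


@njit(cache=True)
def _a_coef(n, x, t):
    nph = n + 0.5
    if x <= t:
        return (
            math.pi
            * nph
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * nph * nph / x)
        )
    return math.pi * nph * math.exp(-0.5 * nph * nph * math.pi * math.pi * x)


@njit(cache=True)
def _trunc_inv_gauss(z, t):
    """Sample IG(mu=1/z, lambda=1) truncated to (0, t]; z >= 0."""
    if z * t < 1.0:  # mu > t: one-sided-stable proposal with exp tilt
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            yv = np.random.standard_normal()
            yv = yv * yv
            x = mu + 0.5 * mu * mu * yv - 0.5 * mu * math.sqrt(
                4.0 * mu * yv + (mu * yv) * (mu * yv)
            )
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def pg_draw(z):
    """One exact PG(1, z) draw."""
    z = 0.5 * abs(z)
    t = _TRUNC
    k = 0.125 * math.pi * math.pi + 0.5 * z * z
    p = 0.5 * math.pi / k * math.exp(-k * t)
    q = 2.0 * math.exp(-z) * _pigauss(t, z)
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = t + np.random.exponential(1.0) / k
        else:
            x = _trunc_inv_gauss(z, t)
        s = _a_coef(0, x, t)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x, t)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x, t)
                if y > s:
                    break


@njit(cache=True)
def pg_draw_many(zs, seed):
    """Seeded vector of PG(1, z) draws (used by tests)."""
    np.random.seed(seed)
    out = np.empty(zs.shape[0])
    for i in range(zs.shape[0]):
        out[i] = pg_draw(zs[i])
    return out


# ---------------------------------------------------------------------------
# small conjugate-draw helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _inv_gamma(shape, rate):
    return rate / np.random.gamma(shape, 1.0)


@njit(cache=True)
def _inv_wishart_2x2(df, psi):
    """Draw 2x2 inverse-Wishart(df, psi) via Bartlett on psi^-1."""
    det = psi[0, 0] * psi[1, 1] - psi[0, 1] * psi[1, 0]
    vi00 = psi[1, 1] / det
    vi01 = -psi[0, 1] / det
    vi11 = psi[0, 0] / det
    # cholesky of psi^-1
    l00 = math.sqrt(vi00)
    l10 = vi01 / l00
    l11 = math.sqrt(vi11 - l10 * l10)
    # Bartlett factor
    a00 = math.sqrt(2.0 * np.random.gamma(0.5 * df, 1.0))
    a11 = math.sqrt(2.0 * np.random.gamma(0.5 * (df - 1.0), 1.0))
    a10 = np.random.standard_normal()
    # T = L @ A (lower); W = T T'
    t00 = l00 * a00
    t10 = l10 * a00 + l11 * a10
    t11 = l11 * a11
    w00 = t00 * t00
    w10 = t10 * t00
    w11 = t10 * t10 + t11 * t11
    dw = w00 * w11 - w10 * w10
    g = np.empty((2, 2))
    g[0, 0] = w11 / dw
    g[0, 1] = -w10 / dw
    g[1, 0] = -w10 / dw
    g[1, 1] = w00 / dw
    return g


# ---------------------------------------------------------------------------
# main Gibbs kernel
# ---------------------------------------------------------------------------

MODE_INTERCEPT = 0   # univariate breeding values (basic animal model)
MODE_SLOPE = 1       # bivariate intercept + slope breeding values
MODE_SLOPE_FROZEN = 2  # slope machinery present but a2 pinned to zero


@njit(cache=True)
def run_chain(
    seed,
    y,
    X,
    cage_idx,
    n_cages,
    zcov,
    mode,
    ainv_indptr,
    ainv_indices,
    ainv_data,
    ainv_diag,
    prior_scale,
    v_r,
    n_warmup,
    n_iter,
    thin,
    slope_col,
):
    """Run one MCMC chain; returns (kept, npar) array.

    Parameter columns: p fixed effects, then V_C, V_A_I, V_A_S, C_A_IS
    (slope columns zero in intercept-only/frozen modes).  ``slope_col`` is
    the index of the fixed-effect column equal to the slope covariate (-1
    if absent); it enables the slope translation interweaving move.

    Mixing of variance components under the centered parametrization is
    poor, so each sweep ends with interweaving moves: exact translation
    (location shuttled between the intercept and each zero-mean random
    field) and ancillarity-sufficiency rescaling of the genetic standard
    deviations (Gaussian proposal from the whitened likelihood, accepted
    on the prior ratio).
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    nu = _HALF_T_NU

    kappa = y - 0.5
    b = np.zeros(p)
    c = np.zeros(n_cages)
    e = np.zeros(n)
    a1 = np.zeros(n)
    a2 = np.zeros(n)
    omega = np.full(n, 0.25)
    v_c = 0.5
    lam_c = 1.0
    g11 = 0.5
    if mode == MODE_SLOPE:
        g22 = 0.1
    elif mode == MODE_SLOPE_FROZEN:
        g22 = 1e-10  # pinned: slope machinery runs but a2 is shrunk to zero
    else:
        g22 = 0.0
    g12 = 0.0
    lam_1 = 1.0
    lam_2 = 1.0

    n_keep = (n_iter - n_warmup + thin - 1) // thin
    out = np.empty((n_keep, p + 4))
    kept = 0

    eta = np.zeros(n)
    sc2 = prior_scale * prior_scale

    # total precision mass of A^-1 (for translation moves): 1' A^-1 1
    s_one = 0.0
    for i in range(n):
        s_one += ainv_diag[i]
    for ptr in range(ainv_data.shape[0]):
        s_one += ainv_data[ptr]

    for it in range(n_iter):
        # full linear predictor (recomputed each sweep; avoids drift)
        for i in range(n):
            acc = 0.0
            for j in range(p):
                acc += X[i, j] * b[j]
            acc += c[cage_idx[i]] + a1[i] + e[i]
            if mode != MODE_INTERCEPT:
                acc += a2[i] * zcov[i]
            eta[i] = acc

        # --- Polya-Gamma auxiliaries
        for i in range(n):
            omega[i] = pg_draw(eta[i])

        # --- fixed effects (flat prior)
        M = np.zeros((p, p))
        v = np.zeros(p)
        for i in range(n):
            r = eta[i]
            for j in range(p):
                r -= X[i, j] * b[j]
            wi = omega[i]
            resid = kappa[i] - wi * r
            for j in range(p):
                v[j] += X[i, j] * resid
                for k in range(p):
                    M[j, k] += wi * X[i, j] * X[i, k]
        L = np.linalg.cholesky(M)
        mean = np.linalg.solve(M, v)
        zr = np.random.standard_normal(p)
        bn = mean + np.linalg.solve(L.T.copy(), zr)
        for i in range(n):
            for j in range(p):
                eta[i] += X[i, j] * (bn[j] - b[j])
        for j in range(p):
            b[j] = bn[j]

        # --- cage effects
        sw = np.zeros(n_cages)
        sl = np.zeros(n_cages)
        for i in range(n):
            ci = cage_idx[i]
            sw[ci] += omega[i]
            sl[ci] += kappa[i] - omega[i] * (eta[i] - c[ci])
        for jc in range(n_cages):
            prec = sw[jc] + 1.0 / v_c
            cn = sl[jc] / prec + np.random.standard_normal() / math.sqrt(prec)
            sl[jc] = cn - c[jc]  # reuse as delta
            c[jc] = cn
        for i in range(n):
            eta[i] += sl[cage_idx[i]]

        # --- individual residual (variance fixed to v_r)
        for i in range(n):
            prec = omega[i] + 1.0 / v_r
            lin = kappa[i] - omega[i] * (eta[i] - e[i])
            en = lin / prec + np.random.standard_normal() / math.sqrt(prec)
            eta[i] += en - e[i]
            e[i] = en

        # --- breeding values, single site against sparse A^-1
        if mode != MODE_INTERCEPT:
            det_g = g11 * g22 - g12 * g12
            gi11 = g22 / det_g
            gi12 = -g12 / det_g
            gi22 = g11 / det_g
            for i in range(n):
                nb1 = 0.0
                nb2 = 0.0
                for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    jj = ainv_indices[ptr]
                    nb1 += ainv_data[ptr] * a1[jj]
                    nb2 += ainv_data[ptr] * a2[jj]
                dii = ainv_diag[i]
                zi = zcov[i]
                wi = omega[i]
                p11 = dii * gi11 + wi
                p12 = dii * gi12 + wi * zi
                p22 = dii * gi22 + wi * zi * zi
                base = kappa[i] - wi * (eta[i] - a1[i] - a2[i] * zi)
                l1 = -(gi11 * nb1 + gi12 * nb2) + base
                l2 = -(gi12 * nb1 + gi22 * nb2) + base * zi
                # 2x2 cholesky solve + sample
                c11 = math.sqrt(p11)
                c21 = p12 / c11
                c22 = math.sqrt(p22 - c21 * c21)
                # mean: solve P m = l
                t1 = l1 / c11
                t2 = (l2 - c21 * t1) / c22
                m2 = t2 / c22
                m1 = (t1 - c21 * m2) / c11
                # sample: m + C^-T z
                z2 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                s2 = z2 / c22
                s1 = (z1 - c21 * s2) / c11
                new1 = m1 + s1
                new2 = m2 + s2
                eta[i] += (new1 - a1[i]) + (new2 - a2[i]) * zi
                a1[i] = new1
                a2[i] = new2
        else:
            for i in range(n):
                nb1 = 0.0
                for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    nb1 += ainv_data[ptr] * a1[ainv_indices[ptr]]
                wi = omega[i]
                prec = ainv_diag[i] / g11 + wi
                lin = -nb1 / g11 + kappa[i] - wi * (eta[i] - a1[i])
                new1 = lin / prec + np.random.standard_normal() / math.sqrt(prec)
                eta[i] += new1 - a1[i]
                a1[i] = new1

        # --- cage variance (half-t(nu, scale) via Huang-Wand)
        ssc = 0.0
        for jc in range(n_cages):
            ssc += c[jc] * c[jc]
        v_c = _inv_gamma(0.5 * (nu + n_cages), nu / lam_c + 0.5 * ssc)
        lam_c = _inv_gamma(0.5 * (nu + 1.0), nu / v_c + 1.0 / sc2)

        # --- genetic (co)variances: S = a' A^-1 a
        s11 = 0.0
        s12 = 0.0
        s22 = 0.0
        for i in range(n):
            r1 = ainv_diag[i] * a1[i]
            r2 = ainv_diag[i] * a2[i]
            for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
                jj = ainv_indices[ptr]
                r1 += ainv_data[ptr] * a1[jj]
                r2 += ainv_data[ptr] * a2[jj]
            s11 += a1[i] * r1
            s12 += a1[i] * r2
            s22 += a2[i] * r2
        if mode == MODE_SLOPE:
            psi = np.empty((2, 2))
            psi[0, 0] = 2.0 * nu / lam_1 + s11
            psi[0, 1] = s12
            psi[1, 0] = s12
            psi[1, 1] = 2.0 * nu / lam_2 + s22
            g = _inv_wishart_2x2(nu + 1.0 + n, psi)
            g11 = g[0, 0]
            g12 = g[0, 1]
            g22 = g[1, 1]
            det_g = g11 * g22 - g12 * g12
            gi11 = g22 / det_g
            gi22 = g11 / det_g
            lam_1 = _inv_gamma(0.5 * (nu + 2.0), nu * gi11 + 1.0 / sc2)
            lam_2 = _inv_gamma(0.5 * (nu + 2.0), nu * gi22 + 1.0 / sc2)
        else:
            g11 = _inv_gamma(0.5 * (nu + n), nu / lam_1 + 0.5 * s11)
            lam_1 = _inv_gamma(0.5 * (nu + 1.0), nu / g11 + 1.0 / sc2)

        # --- ASIS rescaling of the genetic SD(s)
        if mode == MODE_SLOPE:
            sig1 = math.sqrt(g11)
            sig2 = math.sqrt(g22)
            rho = g12 / (sig1 * sig2)
            if rho > 0.999:
                rho = 0.999
            if rho < -0.999:
                rho = -0.999
            one_m_r2 = 1.0 - rho * rho
            # sigma_1 (intercept SD)
            if sig1 > 1e-8:
                prec_l = 0.0
                lin_l = 0.0
                for i in range(n):
                    w = a1[i] / sig1
                    prec_l += omega[i] * w * w
                    lin_l += w * (kappa[i] - omega[i] * (eta[i] - a1[i]))
                if prec_l > 1e-12:
                    prop = lin_l / prec_l + np.random.standard_normal() / math.sqrt(prec_l)
                    if abs(prop) > 1e-8:
                        psi1 = 2.0 * nu / lam_1
                        f_old = -5.0 * math.log(sig1) - psi1 / (2.0 * one_m_r2 * sig1 * sig1)
                        f_new = -5.0 * math.log(abs(prop)) - psi1 / (2.0 * one_m_r2 * prop * prop)
                        if math.log(np.random.random()) < f_new - f_old:
                            ratio = prop / sig1
                            for i in range(n):
                                eta[i] += (prop - sig1) * (a1[i] / sig1)
                                a1[i] *= ratio
                            g11 = prop * prop
                            g12 = rho * prop * sig2
                            sig1 = abs(prop)
            # sigma_2 (slope SD); sign flips are absorbed by the a2 field
            rho = g12 / (sig1 * sig2)
            if rho > 0.999:
                rho = 0.999
            if rho < -0.999:
                rho = -0.999
            one_m_r2 = 1.0 - rho * rho
            if sig2 > 1e-8:
                prec_l = 0.0
                lin_l = 0.0
                for i in range(n):
                    wz = (a2[i] / sig2) * zcov[i]
                    prec_l += omega[i] * wz * wz
                    lin_l += wz * (kappa[i] - omega[i] * (eta[i] - a2[i] * zcov[i]))
                if prec_l > 1e-12:
                    prop = lin_l / prec_l + np.random.standard_normal() / math.sqrt(prec_l)
                    if abs(prop) > 1e-8:
                        psi2 = 2.0 * nu / lam_2
                        f_old = -5.0 * math.log(sig2) - psi2 / (2.0 * one_m_r2 * sig2 * sig2)
                        f_new = -5.0 * math.log(abs(prop)) - psi2 / (2.0 * one_m_r2 * prop * prop)
                        if math.log(np.random.random()) < f_new - f_old:
                            ratio = prop / sig2
                            for i in range(n):
                                eta[i] += (prop - sig2) * (a2[i] / sig2) * zcov[i]
                                a2[i] *= ratio
                            g22 = prop * prop
                            g12 = rho * sig1 * prop
        else:
            sig1 = math.sqrt(g11)
            if sig1 > 1e-8:
                prec_l = 0.0
                lin_l = 0.0
                for i in range(n):
                    w = a1[i] / sig1
                    prec_l += omega[i] * w * w
                    lin_l += w * (kappa[i] - omega[i] * (eta[i] - a1[i]))
                if prec_l > 1e-12:
                    prop = lin_l / prec_l + np.random.standard_normal() / math.sqrt(prec_l)
                    if abs(prop) > 1e-8:
                        f_old = -(nu + 1.0) * math.log(sig1) - nu / (lam_1 * sig1 * sig1)
                        f_new = -(nu + 1.0) * math.log(abs(prop)) - nu / (lam_1 * prop * prop)
                        if math.log(np.random.random()) < f_new - f_old:
                            ratio = prop / sig1
                            for i in range(n):
                                eta[i] += (prop - sig1) * (a1[i] / sig1)
                                a1[i] *= ratio
                            g11 = prop * prop

        # --- ASIS rescaling of the cage SD
        sigc = math.sqrt(v_c)
        if sigc > 1e-8:
            prec_l = 0.0
            lin_l = 0.0
            for i in range(n):
                w = c[cage_idx[i]] / sigc
                prec_l += omega[i] * w * w
                lin_l += w * (kappa[i] - omega[i] * (eta[i] - c[cage_idx[i]]))
            if prec_l > 1e-12:
                prop = lin_l / prec_l + np.random.standard_normal() / math.sqrt(prec_l)
                if abs(prop) > 1e-8:
                    f_old = -(nu + 1.0) * math.log(sigc) - nu / (lam_c * sigc * sigc)
                    f_new = -(nu + 1.0) * math.log(abs(prop)) - nu / (lam_c * prop * prop)
                    if math.log(np.random.random()) < f_new - f_old:
                        ratio = prop / sigc
                        for i in range(n):
                            eta[i] += (prop - sigc) * (c[cage_idx[i]] / sigc)
                        for jc in range(n_cages):
                            c[jc] *= ratio
                        v_c = prop * prop

        # --- exact Gibbs on the slope-on-intercept genetic regression
        # reparametrize a2 = kap * a1 + d;  kap | g11, v_d ~ N(0, v_d/psi1)
        if mode == MODE_SLOPE:
            v_d = g22 - g12 * g12 / g11
            if v_d > 1e-12:
                kap_cur = g12 / g11
                psi1 = 2.0 * nu / lam_1
                prec_l = psi1 / v_d
                lin_l = 0.0
                for i in range(n):
                    w = a1[i] * zcov[i]
                    prec_l += omega[i] * w * w
                    lin_l += w * (kappa[i] - omega[i] * (eta[i] - kap_cur * w))
                kap_new = lin_l / prec_l + np.random.standard_normal() / math.sqrt(prec_l)
                for i in range(n):
                    eta[i] += (kap_new - kap_cur) * a1[i] * zcov[i]
                    a2[i] += (kap_new - kap_cur) * a1[i]
                g12 = kap_new * g11
                g22 = kap_new * kap_new * g11 + v_d

        # --- translation interweaving (eta is invariant by construction)
        # intercept <-> cage field
        cbar = 0.0
        for jc in range(n_cages):
            cbar += c[jc]
        cbar /= n_cages
        t = cbar + np.random.standard_normal() * math.sqrt(v_c / n_cages)
        for jc in range(n_cages):
            c[jc] -= t
        b[0] += t
        # intercept <-> latent residual field
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        t = ebar + np.random.standard_normal() * math.sqrt(v_r / n)
        for i in range(n):
            e[i] -= t
        b[0] += t
        # intercept <-> genetic intercept field (and slope <-> genetic slope)
        u1 = 0.0
        u2 = 0.0
        for i in range(n):
            r1 = ainv_diag[i] * a1[i]
            r2 = ainv_diag[i] * a2[i]
            u1 += r1
            u2 += r2
        for i in range(n):
            for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
                jj = ainv_indices[ptr]
                u1 += ainv_data[ptr] * a1[jj]
                u2 += ainv_data[ptr] * a2[jj]
        if mode == MODE_SLOPE:
            det_g = g11 * g22 - g12 * g12
            gi11 = g22 / det_g
            gi12 = -g12 / det_g
            gi22 = g11 / det_g
        else:
            gi11 = 1.0 / g11
            gi12 = 0.0
            gi22 = 0.0
        coef = gi11 * s_one
        lin = gi11 * u1 + gi12 * u2
        t = lin / coef + np.random.standard_normal() / math.sqrt(coef)
        for i in range(n):
            a1[i] -= t
        b[0] += t
        u1 -= t * s_one
        if mode == MODE_SLOPE and slope_col >= 0:
            coef = gi22 * s_one
            lin = gi22 * u2 + gi12 * u1
            t = lin / coef + np.random.standard_normal() / math.sqrt(coef)
            for i in range(n):
                a2[i] -= t
            b[slope_col] += t

        # --- store
        if it >= n_warmup and (it - n_warmup) % thin == 0:
            for j in range(p):
                out[kept, j] = b[j]
            out[kept, p] = v_c
            out[kept, p + 1] = g11
            out[kept, p + 2] = g22 if mode == MODE_SLOPE else 0.0
            out[kept, p + 3] = g12 if mode == MODE_SLOPE else 0.0
            kept += 1

    return out[:kept]
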