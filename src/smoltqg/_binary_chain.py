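"""Compiled Gibbs chain for the univariate logit-link threshold animal model.

The whole iteration loop runs inside numba: Pólya-Gamma latents, fixed
effects, single-site random-term updates against the sparse
relationship-matrix inverse, the latent unit-variance residual, conjugate
inverse-gamma variance draws, and the interweaved (non-centered) scale
move that fixes the slow mixing between breeding-value scale and V_A.
Semantics match the generic sampler in :mod:`smoltqg.mcmc`; only the RNG
stream differs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from smoltqg._polya_gamma import sample_pg1


@njit(cache=True)
def run_chain_binary_univariate(
    kappa,          # (n,) y - 1/2
    X,              # (n, p) fixed design
    lev_mat,        # (k, n) per-term level index per observation, -1 = none
    q_arr,          # (k,) levels per term
    u_off,          # (k+1,) offsets into u_cat
    indptr_cat,     # concatenated CSR indptr (k segments, each q_t+1 long)
    ip_off,         # (k+1,) offsets into indptr_cat
    indices_cat,
    data_cat,
    nz_off,         # (k+1,) offsets into indices/data per term
    prior_nu,
    prior_scale,    # (k,) inverse-gamma prior scale (nu * V0) per term
    n_iter,
    burnin,
    thin,
    seed,
    joint_e_term,   # index of the individual-level (animal) term whose site
                    # update samples (a_i, e_i) jointly, or -1
    lev_inv,        # (q_animal,) observation index per animal level, -1 = none
    interweave,     # enable the global scale move (see module notes: off by
                    # default for binary responses)
):
    np.random.seed(seed)
    n, p = X.shape
    k = q_arr.shape[0]
    n_ret = (n_iter - burnin) // thin

    beta = np.zeros(p)
    u_cat = np.zeros(u_off[k])
    V = prior_scale / prior_nu  # start at the prior scale V0
    e = np.zeros(n)
    eta = np.zeros(n)
    omega = np.ones(n)
    z = np.zeros(n)

    out = np.empty((n_ret, k))
    dev_out = np.empty(n_ret)
    eta_sum = np.zeros(n)
    ret = 0

    XtWX = np.empty((p, p))
    rhs = np.empty(p)

    for it in range(n_iter):
        # Pólya-Gamma latents and pseudo-data
        for i in range(n):
            omega[i] = sample_pg1(eta[i])
            z[i] = kappa[i] / omega[i]

        # fixed effects: beta | rest ~ N((X'WX)^-1 X'W r, (X'WX)^-1)
        for a in range(p):
            rhs[a] = 0.0
            for b in range(p):
                XtWX[a, b] = 0.0
        for i in range(n):
            r_i = z[i] - eta[i]
            for a in range(p):
                x_a = X[i, a]
                r_i += x_a * beta[a]
            # r_i now = z - (eta - X beta)
            for a in range(p):
                w_x = omega[i] * X[i, a]
                rhs[a] += w_x * r_i
                for b in range(p):
                    XtWX[a, b] += w_x * X[i, b]
        L = np.linalg.cholesky(XtWX)
        mu_b = np.linalg.solve(XtWX, rhs)
        xi = np.empty(p)
        for a in range(p):
            xi[a] = np.random.standard_normal()
        # solve L^T d = xi
        d = np.linalg.solve(L.T, xi)
        for i in range(n):
            delta = 0.0
            for a in range(p):
                delta += X[i, a] * (mu_b[a] + d[a] - beta[a])
            eta[i] += delta
        for a in range(p):
            beta[a] = mu_b[a] + d[a]

        # random terms: single-site updates (each observation belongs to at
        # most one level per term, so the per-level W/B accumulations stay
        # exact throughout the site sweep)
        for t in range(k):
            q = q_arr[t]
            W = np.zeros(q)
            B = np.zeros(q)
            lev = lev_mat[t]
            u = u_cat[u_off[t]:u_off[t + 1]]
            contrib_old = np.zeros(n)
            for i in range(n):
                j = lev[i]
                if j >= 0:
                    contrib_old[i] = u[j]
                    r = z[i] - eta[i] + u[j]
                    W[j] += omega[i]
                    B[j] += omega[i] * r
            indptr = indptr_cat[ip_off[t]:ip_off[t + 1]]
            indices = indices_cat[nz_off[t]:nz_off[t + 1]]
            data = data_cat[nz_off[t]:nz_off[t + 1]]
            ginv = 1.0 / V[t]
            if t == joint_e_term:
                # breeding value and latent residual are both
                # individual-level; sampling them jointly removes the slow
                # random walk along a_i + e_i = const
                for j in range(q):
                    s = 0.0
                    ajj = 0.0
                    for ptr in range(indptr[j], indptr[j + 1]):
                        kk = indices[ptr]
                        if kk == j:
                            ajj = data[ptr]
                        else:
                            s += data[ptr] * u[kk]
                    p_a = ajj * ginv
                    i_obs = lev_inv[j]
                    if i_obs < 0:
                        mu = (-ginv * s) / p_a
                        u[j] = mu + np.random.standard_normal() / np.sqrt(p_a)
                        continue
                    w_i = omega[i_obs]
                    c = eta[i_obs] - u[j] - e[i_obs]
                    lin = kappa[i_obs] - w_i * c
                    # precision [[p_a + w, w], [w, 1 + w]]
                    m00 = p_a + w_i
                    m01 = w_i
                    m11 = 1.0 + w_i
                    r0 = -ginv * s + lin
                    r1 = lin
                    l00 = np.sqrt(m00)
                    l10 = m01 / l00
                    l11 = np.sqrt(m11 - l10 * l10)
                    z0 = r0 / l00
                    z1 = (r1 - l10 * z0) / l11
                    mu1 = z1 / l11
                    mu0 = (z0 - l10 * mu1) / l00
                    x0 = np.random.standard_normal()
                    x1 = np.random.standard_normal()
                    d1 = x1 / l11
                    d0 = (x0 - l10 * d1) / l00
                    new_a = mu0 + d0
                    new_e = mu1 + d1
                    eta[i_obs] += (new_a - u[j]) + (new_e - e[i_obs])
                    u[j] = new_a
                    e[i_obs] = new_e
                continue  # eta already updated in place
            for j in range(q):
                s = 0.0
                ajj = 0.0
                for ptr in range(indptr[j], indptr[j + 1]):
                    kk = indices[ptr]
                    if kk == j:
                        ajj = data[ptr]
                    else:
                        s += data[ptr] * u[kk]
                prec = ajj * ginv + W[j]
                mu = (-ginv * s + B[j]) / prec
                u[j] = mu + np.random.standard_normal() / np.sqrt(prec)
            for i in range(n):
                j = lev[i]
                if j >= 0:
                    eta[i] += u[j] - contrib_old[i]

        # latent residual e (variance fixed at 1); when the animal-term
        # joint update already refreshed e this sweep, this is a cheap
        # extra Gibbs pass and remains valid
        if joint_e_term < 0:
            for i in range(n):
                m = eta[i] - e[i]
                prec = omega[i] + 1.0
                mu = (kappa[i] - omega[i] * m) / prec
                new_e = mu + np.random.standard_normal() / np.sqrt(prec)
                eta[i] += new_e - e[i]
                e[i] = new_e

        # variances: V_t | u ~ IG((nu+q)/2, (nu*V0 + u'Ainv u)/2)
        for t in range(k):
            q = q_arr[t]
            u = u_cat[u_off[t]:u_off[t + 1]]
            indptr = indptr_cat[ip_off[t]:ip_off[t + 1]]
            indices = indices_cat[nz_off[t]:nz_off[t + 1]]
            data = data_cat[nz_off[t]:nz_off[t + 1]]
            S = 0.0
            for j in range(q):
                for ptr in range(indptr[j], indptr[j + 1]):
                    S += u[j] * data[ptr] * u[indices[ptr]]
            df = prior_nu + q
            scale = prior_scale[t] + S
            g = np.random.gamma(df / 2.0, 1.0)
            V[t] = scale / (2.0 * g)

        # interweaving scale move per term (non-centered Gibbs on sqrt(V))
        for t in range(k if interweave else 0):
            lev = lev_mat[t]
            u = u_cat[u_off[t]:u_off[t + 1]]
            prec_c = 0.0
            lin = 0.0
            for i in range(n):
                j = lev[i]
                if j >= 0:
                    g_i = u[j]
                    prec_c += omega[i] * g_i * g_i
                    lin += g_i * omega[i] * (z[i] - (eta[i] - g_i))
            if prec_c <= 0.0:
                continue
            mu_c = lin / prec_c
            c = mu_c + np.random.standard_normal() / np.sqrt(prec_c)
            if c <= 1e-6:
                continue
            V_new = c * c * V[t]
            # acceptance: prior x Jacobian ratio, IG prior on V
            log_alpha = (
                -(prior_nu + 1.0) * np.log(c)
                - 0.5 * prior_scale[t] * (1.0 / V_new - 1.0 / V[t])
            )
            if np.log(np.random.random() + 1e-300) < log_alpha:
                for j in range(u.shape[0]):
                    u[j] *= c
                V[t] = V_new
                for i in range(n):
                    j = lev[i]
                    if j >= 0:
                        eta[i] += (c - 1.0) * (u[j] / c)
        # record
        if it >= burnin and (it - burnin) % thin == 0 and ret < n_ret:
            for t in range(k):
                out[ret, t] = V[t]
            dev = 0.0
            for i in range(n):
                # -2 log Bernoulli(y | logistic(eta))
                le = eta[i]
                log1p_exp = np.log1p(np.exp(-np.abs(le))) + max(-le, 0.0)
                y_i = kappa[i] + 0.5
                dev += -2.0 * (-log1p_exp - (1.0 - y_i) * le)
            dev_out[ret] = dev
            for i in range(n):
                eta_sum[i] += eta[i]
            ret += 1

    return out, dev_out, eta_sum, ret
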