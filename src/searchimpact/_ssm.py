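"""Compiled state-space kernels.

Hot loops shared by the structural time-series sampler and the dynamic
mixture filter: a univariate-observation Kalman filter, the Durbin-Koopman
mean-correction simulation smoother (robust to zero innovation variances,
unlike backward-sampling recursions that invert predicted covariances), a
conjugate spike-and-slab subset scan, and the per-component recursions of
the covariate-subset mixture.  All state innovation covariances are diagonal
here, passed as per-time diagonal vectors.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_F_TINY = 1e-12


@njit(cache=True)
def kalman_filter_core(y, mask, Z, T, c, Qdiag, H, a0, P0):
    """Filter a univariate series through a linear-Gaussian state space.

    Returns predicted and filtered state means/covariances, innovations,
    innovation variances, gain, a per-time "updated" flag and the
    log-likelihood.  ``Qdiag`` is (n, m) of diagonal state-innovation
    variances; ``H`` is (n,) observation variances; ``c`` a transition
    offset.  Masked or numerically degenerate observations get
    prediction-only updates.
    """
    n = y.shape[0]
    m = a0.shape[0]
    apred = np.zeros((n, m))
    Ppred = np.zeros((n, m, m))
    att = np.zeros((n, m))
    Ptt = np.zeros((n, m, m))
    v = np.zeros(n)
    F = np.zeros(n)
    Kg = np.zeros((n, m))
    used = np.zeros(n, np.int8)
    a = a0.copy()
    P = P0.copy()
    loglik = 0.0
    for t in range(n):
        apred[t] = a
        Ppred[t] = P
        PZ = P @ Z
        Ft = Z @ PZ + H[t]
        if mask[t] and Ft > _F_TINY:
            vt = y[t] - Z @ a
            K = PZ / Ft
            a = a + K * vt
            # Joseph-free update; symmetrize below
            for i in range(m):
                for j in range(m):
                    P[i, j] = P[i, j] - K[i] * PZ[j]
            v[t] = vt
            F[t] = Ft
            Kg[t] = K
            used[t] = 1
            loglik += -0.5 * (np.log(2.0 * np.pi * Ft) + vt * vt / Ft)
        att[t] = a
        Ptt[t] = P
        # time update
        a = T @ a + c
        P = T @ P @ T.T
        for i in range(m):
            P[i, i] += Qdiag[t, i]
        for i in range(m):
            for j in range(i):
                s = 0.5 * (P[i, j] + P[j, i])
                P[i, j] = s
                P[j, i] = s
    return apred, Ppred, att, Ptt, v, F, Kg, used, loglik


@njit(cache=True)
def smooth_core(y, mask, Z, T, c, Qdiag, H, a0, P0):
    """Smoothed state means E[alpha_t | y] via the r-recursion."""
    n = y.shape[0]
    m = a0.shape[0]
    apred = np.zeros((n, m))
    Ppred = np.zeros((n, m, m))
    v = np.zeros(n)
    F = np.zeros(n)
    TK = np.zeros((n, m))  # K_t in prediction form: T P Z'/F
    used = np.zeros(n, np.int8)
    a = a0.copy()
    P = P0.copy()
    loglik = 0.0
    for t in range(n):
        apred[t] = a
        Ppred[t] = P
        PZ = P @ Z
        Ft = Z @ PZ + H[t]
        if mask[t] and Ft > _F_TINY:
            vt = y[t] - Z @ a
            K = (T @ PZ) / Ft
            a = T @ a + c + K * vt
            L = T.copy()
            for i in range(m):
                for j in range(m):
                    L[i, j] -= K[i] * Z[j]
            P = T @ P @ L.T
            v[t] = vt
            F[t] = Ft
            TK[t] = K
            used[t] = 1
            loglik += -0.5 * (np.log(2.0 * np.pi * Ft) + vt * vt / Ft)
        else:
            a = T @ a + c
            P = T @ P @ T.T
        for i in range(m):
            P[i, i] += Qdiag[t, i]
        for i in range(m):
            for j in range(i):
                s = 0.5 * (P[i, j] + P[j, i])
                P[i, j] = s
                P[j, i] = s
    alphahat = np.zeros((n, m))
    r = np.zeros(m)
    for t in range(n - 1, -1, -1):
        if used[t]:
            # r_{t-1} = Z v/F + L' r,  L' r = T' r - Z (K . r)
            Tr = T.T @ r
            kr = 0.0
            for i in range(m):
                kr += TK[t, i] * r[i]
            r = Tr - Z * kr + Z * (v[t] / F[t])
        else:
            r = T.T @ r
        alphahat[t] = apred[t] + Ppred[t] @ r
    return alphahat, loglik


@njit(cache=True)
def dk_simulate(Z, T, c, Qdiag, H, a0, P0L, z_init, z_state, z_obs):
    """Draw an unconditional state path and observations from the model."""
    n = z_obs.shape[0]
    m = a0.shape[0]
    alpha = np.zeros((n, m))
    yplus = np.zeros(n)
    a = a0 + P0L @ z_init
    for t in range(n):
        alpha[t] = a
        yplus[t] = Z @ a + np.sqrt(H[t]) * z_obs[t]
        a = T @ a + c
        for i in range(m):
            a[i] += np.sqrt(Qdiag[t, i]) * z_state[t, i]
    return alpha, yplus


@njit(cache=True)
def dk_draw(y, mask, Z, T, c, Qdiag, H, a0, P0, P0L, z_init, z_state, z_obs):
    """One posterior draw of the state path (mean-correction sampler)."""
    alpha_plus, y_plus = dk_simulate(Z, T, c, Qdiag, H, a0, P0L, z_init, z_state, z_obs)
    alphahat, _ = smooth_core(y, mask, Z, T, c, Qdiag, H, a0, P0)
    alphahat_plus, _ = smooth_core(y_plus, mask, Z, T, c, Qdiag, H, a0, P0)
    return alpha_plus + alphahat - alphahat_plus


# ---------------------------------------------------------------- regression


@njit(cache=True)
def _subset_logmarg(XtX, Xty, yty, A, gamma, n_obs, prior_df, prior_ss):
    """Log marginal likelihood of y under the included subset (up to terms
    shared by all subsets)."""
    p = gamma.shape[0]
    k = 0
    for j in range(p):
        if gamma[j]:
            k += 1
    if k == 0:
        return -0.5 * (prior_df + n_obs) * np.log(prior_ss + yty)
    idx = np.empty(k, np.int64)
    pos = 0
    for j in range(p):
        if gamma[j]:
            idx[pos] = j
            pos += 1
    As = np.empty((k, k))
    Ms = np.empty((k, k))
    b = np.empty(k)
    for i in range(k):
        b[i] = Xty[idx[i]]
        for j in range(k):
            As[i, j] = A[idx[i], idx[j]]
            Ms[i, j] = As[i, j] + XtX[idx[i], idx[j]]
    La = np.linalg.cholesky(As)
    Lm = np.linalg.cholesky(Ms)
    logdetA = 0.0
    logdetM = 0.0
    for i in range(k):
        logdetA += 2.0 * np.log(La[i, i])
        logdetM += 2.0 * np.log(Lm[i, i])
    # S_n = yty - b' M^{-1} b via triangular solves
    w = np.linalg.solve(Lm, b)
    quad = 0.0
    for i in range(k):
        quad += w[i] * w[i]
    Sn = yty - quad
    if Sn < 1e-12:
        Sn = 1e-12
    return 0.5 * logdetA - 0.5 * logdetM - 0.5 * (prior_df + n_obs) * np.log(prior_ss + Sn)


@njit(cache=True)
def ssvs_scan(XtX, Xty, yty, A, gamma, n_obs, prior_df, prior_ss, log_prior_odds, u):
    """One Gibbs scan over inclusion indicators (in place)."""
    p = gamma.shape[0]
    for j in range(p):
        gamma[j] = 1
        lm1 = _subset_logmarg(XtX, Xty, yty, A, gamma, n_obs, prior_df, prior_ss)
        gamma[j] = 0
        lm0 = _subset_logmarg(XtX, Xty, yty, A, gamma, n_obs, prior_df, prior_ss)
        d = lm1 - lm0 + log_prior_odds[j]
        if d > 35.0:
            p1 = 1.0
        elif d < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + np.exp(-d))
        gamma[j] = 1 if u[j] < p1 else 0
    return gamma


# ------------------------------------------------------------------ mixture


@njit(cache=True)
def mixture_filter_core(y, X, idx, lens, forgetting, ew_weight, Wdiag, use_W,
                        theta, P, s2, logw):
    """Advance every component model through the whole sample (in place).

    ``idx``/``lens`` give the active design-column indices per component;
    ``theta``/``P``/``s2``/``logw`` are updated in place.  Returns the
    normalized weight path (n, K).
    """
    n = y.shape[0]
    K = lens.shape[0]
    wpath = np.zeros((n, K))
    pred = np.zeros(n)
    logdens = np.zeros(K)
    wprior = np.zeros(K)
    for t in range(n):
        # mixture one-step predictive mean under the entering weights
        mx0 = -1e308
        for k in range(K):
            if logw[k] > mx0:
                mx0 = logw[k]
        tot0 = 0.0
        for k in range(K):
            wprior[k] = np.exp(logw[k] - mx0)
            tot0 += wprior[k]
        for k in range(K):
            p = lens[k]
            yh = 0.0
            for i in range(p):
                yh += X[t, idx[k, i]] * theta[k, i]
            pred[t] += (wprior[k] / tot0) * yh
        for k in range(K):
            p = lens[k]
            # predict: inflate state covariance
            if use_W:
                for i in range(p):
                    P[k, i, i] += Wdiag[idx[k, i]]
            else:
                inv = 1.0 / forgetting
                for i in range(p):
                    for j in range(p):
                        P[k, i, j] *= inv
            # gather design
            yhat = 0.0
            for i in range(p):
                yhat += X[t, idx[k, i]] * theta[k, i]
            # Px and F
            F = s2[k]
            Px = np.zeros(p)
            for i in range(p):
                acc = 0.0
                for j in range(p):
                    acc += P[k, i, j] * X[t, idx[k, j]]
                Px[i] = acc
                F += acc * X[t, idx[k, i]]
            v = y[t] - yhat
            if F < 1e-300:
                logdens[k] = -1e300 if v != 0.0 else 0.0
            else:
                logdens[k] = -0.5 * (np.log(2.0 * np.pi * F) + v * v / F)
                for i in range(p):
                    theta[k, i] += Px[i] * v / F
                for i in range(p):
                    for j in range(p):
                        P[k, i, j] -= Px[i] * Px[j] / F
                s2[k] = ew_weight * s2[k] + (1.0 - ew_weight) * v * v
        # weight update in log space with flooring
        mx = -1e308
        for k in range(K):
            logw[k] += logdens[k]
            if logw[k] > mx:
                mx = logw[k]
        tot = 0.0
        for k in range(K):
            w = np.exp(logw[k] - mx)
            if w < 1e-300:
                w = 1e-300
            wpath[t, k] = w
            tot += w
        for k in range(K):
            wpath[t, k] /= tot
            logw[k] = np.log(wpath[t, k])
    return wpath, pred


@njit(cache=True)
def mixture_forecast_core(X_post, idx, lens, theta, logw):
    """Weight-averaged component forecasts with frozen states and weights."""
    h = X_post.shape[0]
    K = lens.shape[0]
    w = np.empty(K)
    mx = -1e308
    for k in range(K):
        if logw[k] > mx:
            mx = logw[k]
    tot = 0.0
    for k in range(K):
        w[k] = np.exp(logw[k] - mx)
        tot += w[k]
    for k in range(K):
        w[k] /= tot
    out = np.zeros(h)
    for t in range(h):
        for k in range(K):
            p = lens[k]
            yhat = 0.0
            for i in range(p):
                yhat += X_post[t, idx[k, i]] * theta[k, i]
            out[t] += w[k] * yhat
    return out
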