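"""L1-penalized logistic regression path fitter (numba).

glmnet-style proximal Newton: an outer IRLS loop re-expands the binomial
deviance as a weighted least-squares problem, an inner coordinate-descent
loop solves it over the active set, and KKT scans admit new features.
Warm starts carry solutions along the penalty path; the path stops early
once the training deviance is essentially saturated (remaining penalty
values inherit the last solution, as glmnet does).

All fitters take the design matrix transposed (features x samples,
C-contiguous) so per-feature loops stream over contiguous memory.

Supports per-feature penalty multipliers (the randomized penalization used
by the selection-frequency procedure).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_WMIN = 1e-5   # IRLS weight floor
_MU_EPS = 1e-10


@njit(cache=True, fastmath=True)
def _sigmoid(x):
    if x > 30.0:
        x = 30.0
    elif x < -30.0:
        x = -30.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=True)
def _deviance(y, z):
    dev = 0.0
    for i in range(y.size):
        mu = _sigmoid(z[i])
        if mu < _MU_EPS:
            mu = _MU_EPS
        elif mu > 1.0 - _MU_EPS:
            mu = 1.0 - _MU_EPS
        dev += -2.0 * (y[i] * np.log(mu) + (1.0 - y[i]) * np.log(1.0 - mu))
    return dev


@njit(cache=True, fastmath=True)
def lasso_logistic_path(XT, y, pf, lambdas, tol=1e-4, max_outer=25, max_inner=200, dev_stop=0.01):
    """Fit the whole path; returns (intercepts, coefs[n_lambda, p]).

    ``XT`` is features x samples.  The caller standardizes columns for
    glmnet-like behaviour; column scales are nevertheless absorbed exactly
    via weighted squared norms.  ``pf`` are per-feature penalty multipliers.
    """
    p, n = XT.shape
    nl = lambdas.size
    coefs = np.zeros((nl, p))
    icpts = np.zeros(nl)

    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    z = np.full(n, b0)
    w = np.empty(n)
    r = np.empty(n)
    xv = np.zeros(p)
    active = np.zeros(p, np.bool_)
    null_dev = _deviance(y, z)

    li = 0
    while li < nl:
        lam = lambdas[li]
        for outer in range(max_outer):
            # expand the deviance at the current linear predictor
            wsum = 0.0
            for i in range(n):
                pi = _sigmoid(z[i])
                wi = pi * (1.0 - pi)
                if wi < _WMIN:
                    wi = _WMIN
                w[i] = wi
                r[i] = y[i] - pi
                wsum += wi
            wsum /= n
            for j in range(p):
                if active[j]:
                    s = 0.0
                    for i in range(n):
                        s += w[i] * XT[j, i] * XT[j, i]
                    xv[j] = s / n
            outer_change = 0.0
            while True:  # inner CD + KKT admission
                for _ in range(max_inner):
                    maxd = 0.0
                    u0 = 0.0
                    for i in range(n):
                        u0 += r[i]
                    d0 = u0 / (n * wsum)
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            z[i] += d0
                            r[i] -= w[i] * d0
                        if abs(d0) > maxd:
                            maxd = abs(d0)
                    for j in range(p):
                        if not active[j]:
                            continue
                        g = 0.0
                        for i in range(n):
                            g += XT[j, i] * r[i]
                        g /= n
                        u = xv[j] * beta[j] + g
                        t = lam * pf[j]
                        if u > t:
                            bn = (u - t) / xv[j]
                        elif u < -t:
                            bn = (u + t) / xv[j]
                        else:
                            bn = 0.0
                        d = bn - beta[j]
                        if d != 0.0:
                            beta[j] = bn
                            for i in range(n):
                                z[i] += XT[j, i] * d
                                r[i] -= w[i] * XT[j, i] * d
                            if abs(d) > maxd:
                                maxd = abs(d)
                    if maxd > outer_change:
                        outer_change = maxd
                    if maxd < tol:
                        break
                # KKT scan over inactive features
                admitted = False
                for j in range(p):
                    if active[j]:
                        continue
                    g = 0.0
                    for i in range(n):
                        g += XT[j, i] * r[i]
                    g /= n
                    if abs(g) > lam * pf[j]:
                        active[j] = True
                        s = 0.0
                        for i in range(n):
                            s += w[i] * XT[j, i] * XT[j, i]
                        xv[j] = s / n
                        admitted = True
                if not admitted:
                    break
            if outer_change < tol:
                break
        icpts[li] = b0
        for j in range(p):
            coefs[li, j] = beta[j]
        if _deviance(y, z) < dev_stop * null_dev:
            # saturated: remaining penalties inherit this solution
            for lj in range(li + 1, nl):
                icpts[lj] = b0
                for j in range(p):
                    coefs[lj, j] = beta[j]
            break
        li += 1
    return icpts, coefs


@njit(cache=True, fastmath=True)
def _heldout_deviance(XT, y, heldout, icpts, coefs, dev):
    nl = icpts.size
    p = XT.shape[0]
    nh = heldout.size
    eta = np.empty(nh)
    for li in range(nl):
        for k in range(nh):
            eta[k] = icpts[li]
        for j in range(p):
            b = coefs[li, j]
            if b != 0.0:
                for k in range(nh):
                    eta[k] += XT[j, heldout[k]] * b
        for k in range(nh):
            mu = _sigmoid(eta[k])
            if mu < _MU_EPS:
                mu = _MU_EPS
            elif mu > 1.0 - _MU_EPS:
                mu = 1.0 - _MU_EPS
            yi = y[heldout[k]]
            dev[li] += -2.0 * (yi * np.log(mu) + (1.0 - yi) * np.log(1.0 - mu))


@njit(cache=True, fastmath=True)
def one_permutation(XT, y, foldid, n_folds, pf, lambdas, tol=1e-4):
    """One randomized-penalty CV round.

    Fits the path on each training fold, accumulates held-out binomial
    deviance, picks the deviance-minimizing penalty, refits on all rows,
    and returns (nonzero mask at the chosen penalty, chosen index).
    """
    p, n = XT.shape
    nl = lambdas.size
    dev = np.zeros(nl)
    for f in range(n_folds):
        n_tr = 0
        for i in range(n):
            if foldid[i] != f:
                n_tr += 1
        XTt = np.empty((p, n_tr))
        yt = np.empty(n_tr)
        heldout = np.empty(n - n_tr, dtype=np.int64)
        k = 0
        h = 0
        for i in range(n):
            if foldid[i] != f:
                for j in range(p):
                    XTt[j, k] = XT[j, i]
                yt[k] = y[i]
                k += 1
            else:
                heldout[h] = i
                h += 1
        icpts, coefs = lasso_logistic_path(XTt, yt, pf, lambdas, tol)
        _heldout_deviance(XT, y, heldout, icpts, coefs, dev)
    best = 0
    for li in range(1, nl):
        if dev[li] < dev[best]:
            best = li
    icpts, coefs = lasso_logistic_path(XT, y, pf, lambdas, tol)
    mask = np.zeros(p, np.bool_)
    for j in range(p):
        if coefs[best, j] != 0.0:
            mask[j] = True
    return mask, best


def lambda_sequence(X, y, pf, n_lambda=100, lambda_min_ratio=0.01):
    """glmnet-style log-spaced penalty grid from the null-model gradient."""
    n = X.shape[0]
    g = np.abs(X.T @ (y - y.mean())) / n
    with np.errstate(divide="ignore"):
        lam_max = float(np.max(g / pf))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.exp(np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambda))
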