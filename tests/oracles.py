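"""Independent brute-force oracles used to check the library's statistics.

Everything here is deliberately naive (explicit loops, closed forms,
enumeration) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_oracle(x, y):
    """Pearson r, t, two-sided p and Fisher z via explicit formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
    r = num / den
    rc = min(max(r, -(1 - 1e-12)), 1 - 1e-12)
    t = rc * math.sqrt((n - 2) / (1 - rc**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    z = math.atanh(rc) * math.sqrt(n - 3)
    return r, t, p, z


def ols_oracle(D, y):
    """OLS by explicit normal equations: coefficients, se, t, p, residuals."""
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ D.T @ y
    resid = y - D @ beta
    df = len(y) - D.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(sigma2 * DtD_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, resid


def enet_coordinate_descent_oracle(X, y, lam, alpha, n_iter=20000, tol=1e-14):
    """From-scratch coordinate descent for the elastic net.

    Minimizes 1/(2n) ||y - Xb||^2 + lam * (alpha * |b|_1 + (1-alpha)/2 |b|_2^2)
    on standardized predictors (population sd) and centered response, then
    maps coefficients back to the original scale. Matches the convention of
    standard solvers (standardize internally, report original-scale
    coefficients, intercept from the means).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    ym = y.mean()
    yc = y - ym
    b = np.zeros(p)
    resid = yc.copy()
    col_sq = (Xs**2).sum(axis=0) / n
    for _ in range(n_iter):
        max_delta = 0.0
        for j in range(p):
            old = b[j]
            rho = (Xs[:, j] @ resid) / n + col_sq[j] * old
            # soft threshold
            z = abs(rho) - lam * alpha
            new = 0.0 if z <= 0 else math.copysign(z, rho) / (
                col_sq[j] + lam * (1 - alpha)
            )
            if new != old:
                resid += Xs[:, j] * (old - new)
                b[j] = new
                max_delta = max(max_delta, abs(new - old))
        if max_delta < tol:
            break
    coef = b / sd
    intercept = ym - float(coef @ mean)
    return intercept, coef


def hypergeom_pmf(a, row1, row2, col1):
    """P(top-left cell = a) for fixed margins (row1, row2, col1)."""
    return (
        math.comb(row1, a) * math.comb(row2, col1 - a) / math.comb(row1 + row2, col1)
    )


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher exact p by enumerating all tables with the margins.

    Sums the probabilities of every table no more likely than the observed
    one (with the standard relative-epsilon guard against ties lost to
    floating point).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, row1, row2, col1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def stouffer_oracle(zs, ws):
    zs = np.asarray(zs, dtype=float)
    ws = np.asarray(ws, dtype=float)
    return float((ws * zs).sum() / math.sqrt(float((ws**2).sum())))
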