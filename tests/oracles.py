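"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's own code paths: NIPALS iterates the
classical power algorithm, BH is the literal step-up definition, and the
permutation log-rank builds the exact statistic from risk-set counting.
"""

import numpy as np


def nipals_first_weight(X, y, max_iter=500, tol=1e-12):
    """First PLS weight vector by the classical NIPALS iteration.

    Mean-centers X and y, then iterates w = X'u / ||X'u||, t = X w,
    u = y q with q = y't / t't until the weight vector stabilizes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    u = yc.copy()
    w_old = None
    for _ in range(max_iter):
        w = Xc.T @ u
        w = w / np.linalg.norm(w)
        t = Xc @ w
        q = (yc @ t) / (t @ t)
        u = yc * q
        if w_old is not None and np.linalg.norm(w - w_old) < tol:
            break
        w_old = w
    return w


def bh_stepup(p):
    """Brute-force Benjamini–Hochberg: p_adj_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def perm_logrank_chi2(times, events, groups_matrix):
    """Two-group log-rank chi2 for a batch of 0/1 group assignments.

    Vectorized over the rows of ``groups_matrix`` (shape B x n). Assumes
    distinct event times (no ties).
    """
    times = np.asarray(times, dtype=float)
    order = np.argsort(times)
    e = np.asarray(events)[order]
    G = np.asarray(groups_matrix)[:, order]
    n = len(times)
    at_risk = n - np.arange(n)
    n1 = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]
    frac = n1 / at_risk
    O1 = (G * e).sum(axis=1)
    E1 = (frac * e).sum(axis=1)
    V = (frac * (1 - frac) * e).sum(axis=1)
    return (O1 - E1) ** 2 / V
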