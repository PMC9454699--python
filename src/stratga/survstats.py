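"""Small, fast survival and logistic primitives for the fitness inner loop.

The fitness function evaluates thousands of two-group survival comparisons
per GA generation, each on a few dozen patients, so these are implemented as
self-contained numpy routines rather than DataFrame-based fits:

* a two-group Cox proportional-hazards fit (single binary covariate, Breslow
  handling of tied event times, Newton iterations with step halving),
* two-group and k-group log-rank tests (1-df and (k-1)-df chi-square),
* a one-feature logistic regression whose 0.5-probability point is the
  risk-score boundary between two adjacent subtypes.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_BETA_CAP = 20.0  # |log HR| cap under monotone partial likelihood


def _risk_table(time: np.ndarray, event: np.ndarray, group: np.ndarray):
    """Per distinct event time: at-risk and event counts, total and group-1.

    Returns ``(d, d1, n, n1)`` arrays over event times in increasing order.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), group[order]
    n_total = len(t)
    # at-risk counts just before each position, assuming ties share a risk set
    uniq, first = np.unique(t, return_index=True)
    # counts per unique time
    d = np.zeros(len(uniq))
    d1 = np.zeros(len(uniq))
    idx = np.searchsorted(uniq, t)
    np.add.at(d, idx, e)
    np.add.at(d1, idx, e & (g == 1))
    removed = np.zeros(len(uniq))
    removed1 = np.zeros(len(uniq))
    np.add.at(removed, idx, 1.0)
    np.add.at(removed1, idx, (g == 1).astype(float))
    n = n_total - np.concatenate(([0.0], np.cumsum(removed)[:-1]))
    n1 = float(np.sum(g == 1)) - np.concatenate(([0.0], np.cumsum(removed1)[:-1]))
    keep = d > 0
    return d[keep], d1[keep], n[keep], n1[keep]


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_two_group(time, event, group) -> tuple[float, float, float]:
    """Two-group log-rank test.

    Returns ``(observed_minus_expected, chi2, p)`` where the first entry is
    the O-E statistic for group 1 (positive when group 1 has excess events,
    i.e. worse survival).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    d, d1, n, n1 = _risk_table(time, event, group)
    if d.size == 0:
        return 0.0, 0.0, 1.0
    expected = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    var = np.where(n > 1, var, 0.0)
    o_minus_e = float(np.sum(d1 - expected))
    v = float(np.sum(var))
    if v <= 0:
        return o_minus_e, 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / v
    return o_minus_e, chi2, float(stats.chi2.sf(chi2, 1))


def logrank_k_group(time, event, group_labels) -> tuple[float, float, int]:
    """k-sample log-rank test across the distinct labels of ``group_labels``.

    Returns ``(chi2, p, df)``; the statistic is (O-E)' V^- (O-E) over the
    first k-1 groups with the standard hypergeometric covariance.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("k-group log-rank needs at least 2 groups")
    codes = np.searchsorted(uniq, labels)

    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], codes[order]
    ut, idx0 = np.unique(t, return_index=True)
    pos = np.searchsorted(ut, t)
    m = len(ut)
    d_tot = np.zeros(m)
    np.add.at(d_tot, pos, e.astype(float))
    d_grp = np.zeros((m, k))
    np.add.at(d_grp, (pos, g), e.astype(float))
    rem_grp = np.zeros((m, k))
    np.add.at(rem_grp, (pos, g), 1.0)
    n_grp0 = np.bincount(codes, minlength=k).astype(float)
    n_grp = n_grp0 - np.vstack([np.zeros(k), np.cumsum(rem_grp, axis=0)[:-1]])
    n_tot = n_grp.sum(axis=1)

    keep = d_tot > 0
    d_tot, d_grp, n_grp, n_tot = d_tot[keep], d_grp[keep], n_grp[keep], n_tot[keep]
    O = d_grp.sum(axis=0)
    E = (d_tot[:, None] * n_grp / n_tot[:, None]).sum(axis=0)
    # covariance of O over event times
    V = np.zeros((k, k))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n_grp / n_tot[:, None]
        w = d_tot * (n_tot - d_tot) / np.maximum(n_tot - 1.0, 1.0)
    for j in range(len(d_tot)):
        p_j = frac[j]
        V += w[j] * (np.diag(p_j) - np.outer(p_j, p_j))
    z = (O - E)[:-1]
    Vs = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vs, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vs) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return chi2, float(stats.chi2.sf(chi2, df)), df


# ---------------------------------------------------------------------------
# two-group Cox
# ---------------------------------------------------------------------------

def cox_two_group(time, event, group, *, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Log hazard ratio of group 1 vs group 0 under proportional hazards.

    Single binary covariate; Breslow approximation for tied event times;
    Newton's method with step halving on the log partial likelihood.  Under a
    monotone likelihood (perfectly separated event orders) the estimate is
    capped at +/-20, which preserves the sign the fitness function needs.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    d, d1, n, n1 = _risk_table(time, event, group)
    if d.size == 0:
        return 0.0
    n0 = n - n1
    D1 = float(np.sum(d1))

    def loglik(beta: float) -> float:
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        return beta * D1 - float(np.sum(d * np.log(denom)))

    beta = 0.0
    ll = loglik(beta)
    for _ in range(max_iter):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        mu = n1 * eb / denom
        grad = D1 - float(np.sum(d * mu))
        hess = -float(np.sum(d * mu * (1.0 - mu)))
        if hess >= -1e-12:  # flat likelihood (e.g. one group never at risk)
            break
        step = -grad / hess
        new_beta = float(np.clip(beta + step, -_BETA_CAP, _BETA_CAP))
        new_ll = loglik(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = float(np.clip(beta + step, -_BETA_CAP, _BETA_CAP))
            new_ll = loglik(new_beta)
            halvings += 1
        if abs(new_ll - ll) < tol and abs(new_beta - beta) < 1e-6:
            beta, ll = new_beta, new_ll
            break
        beta, ll = new_beta, new_ll
    return beta


# ---------------------------------------------------------------------------
# one-feature logistic regression
# ---------------------------------------------------------------------------

def logistic_boundary(x, y) -> tuple[float, str]:
    """Risk-score value where P(upper subtype) = 0.5 under a 1-D logistic fit.

    ``x`` are risk scores, ``y`` membership of the higher-risk subtype.
    Returns ``(boundary, method)`` where method records which branch produced
    it: "logistic", "separation" (perfectly separated classes -> midpoint of
    the gap) or "median" (non-positive slope -> midpoint of class medians).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both classes must be non-empty")
    if x0.max() < x1.min():  # perfect separation in the expected direction
        return float(0.5 * (x0.max() + x1.min())), "separation"
    if x1.max() < x0.min():  # inverted separation: slope would be negative
        boundary = float(0.5 * (np.median(x0) + np.median(x1)))
        logger.debug("inverted separation in boundary fit; midpoint of medians used")
        return boundary, "median"

    # Newton-IRLS on [intercept, slope]; x centred/scaled for conditioning
    mu_x, sd_x = float(x.mean()), float(x.std())
    sd_x = sd_x if sd_x > 0 else 1.0
    z = (x - mu_x) / sd_x
    w = np.zeros(2)
    X = np.column_stack([np.ones_like(z), z])
    for _ in range(100):
        eta = X @ w
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = X.T @ (y - p)
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            break
        w = w + step
        if np.max(np.abs(grad)) < 1e-10 or np.max(np.abs(step)) < 1e-12:
            break
    b0, b1 = w[0] - w[1] * mu_x / sd_x, w[1] / sd_x
    if b1 <= 0:
        boundary = float(0.5 * (np.median(x0) + np.median(x1)))
        logger.debug("non-positive logistic slope; midpoint of medians used")
        return boundary, "median"
    return float(-b0 / b1), "logistic"
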