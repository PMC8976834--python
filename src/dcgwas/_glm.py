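"""Logistic-regression fitting kernels.

Two routes: a general IRLS fitter for an arbitrary design matrix, and a
vectorised Newton fitter that works from per-variant genotype count
tables (sufficient statistics for the covariate-free additive model),
used for genome-scale null simulations.
"""

from __future__ import annotations

import numpy as np

#: |beta| beyond which a fit is declared (quasi-)separated.
SEPARATION_BOUND = 15.0
MAX_ITER = 50
LOGLIK_TOL = 1e-8


class FitError(RuntimeError):
    """Raised when a logistic fit cannot produce a usable estimate."""


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def irls_logistic(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool, str]:
    """Fit a logistic regression by iteratively reweighted least squares.

    Returns ``(beta, cov, converged, flag)``.  ``flag`` is ``""`` on a
    clean fit, else one of ``"separation"``, ``"no_convergence"``,
    ``"singular"``.  Convergence is declared when the log-likelihood
    improves by less than 1e-8; separation when any |coefficient|
    exceeds 15.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    # start the intercept (first constant column, if any) at the empirical logit
    const_cols = np.where(np.ptp(X, axis=0) == 0)[0]
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    if const_cols.size:
        beta[const_cols[0]] = np.log(ybar / (1 - ybar)) / X[0, const_cols[0]]

    ll_old = _loglik(y, X @ beta)
    flag = "no_convergence"
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, np.full((k, k), np.nan), False, "singular"
        beta_new = beta + step
        ll_new = _loglik(y, X @ beta_new)
        # step-halving if the likelihood worsens
        halves = 0
        while ll_new < ll_old and halves < 10:
            step /= 2.0
            beta_new = beta + step
            ll_new = _loglik(y, X @ beta_new)
            halves += 1
        beta = beta_new
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            return beta, np.full((k, k), np.nan), False, "separation"
        if abs(ll_new - ll_old) < LOGLIK_TOL:
            converged = True
            flag = ""
            ll_old = ll_new
            break
        ll_old = ll_new

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, np.full((k, k), np.nan), False, "singular"
    return beta, cov, converged, flag


def newton_dosage_counts(
    counts_case: np.ndarray, counts_ctrl: np.ndarray, max_iter: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised additive logistic fits from genotype count tables.

    Parameters
    ----------
    counts_case, counts_ctrl
        Arrays of shape (m, 3): per-variant counts of genotypes 0/1/2 in
        cases and controls.  These are the sufficient statistics for the
        model logit P(case) = b0 + b1 * dosage with no covariates.

    Returns
    -------
    (beta, se)
        Per-variant dosage log-odds and Wald standard error; NaN where
        the model is degenerate (monomorphic or separated).
    """
    cc = np.asarray(counts_case, dtype=float)
    cn = np.asarray(counts_ctrl, dtype=float)
    if cc.shape != cn.shape or cc.ndim != 2 or cc.shape[1] != 3:
        raise ValueError("count arrays must both have shape (m, 3)")
    m = cc.shape[0]
    t = cc + cn  # totals per design point
    g = np.array([0.0, 1.0, 2.0])

    tot = t.sum(axis=1)
    ncase = cc.sum(axis=1)
    bad = (ncase == 0) | (ncase == tot)
    # monomorphic dosage: fewer than two distinct genotype values observed
    bad |= (t > 0).sum(axis=1) < 2

    ybar = np.clip(ncase / np.maximum(tot, 1), 1e-6, 1 - 1e-6)
    b0 = np.log(ybar / (1 - ybar))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * g[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = t * mu * (1.0 - mu)
        r = cc - t * mu
        g0 = r.sum(axis=1)
        g1 = (r * g).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * g).sum(axis=1)
        h11 = (w * g * g).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        db0 = np.nan_to_num(db0, nan=0.0)
        db1 = np.nan_to_num(db1, nan=0.0)
        b0 = b0 + np.clip(db0, -5, 5)
        b1 = b1 + np.clip(db1, -5, 5)

    eta = b0[:, None] + b1[:, None] * g[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = t * mu * (1.0 - mu)
    h00 = w.sum(axis=1)
    h01 = (w * g).sum(axis=1)
    h11 = (w * g * g).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(h00 / det)
    bad |= ~np.isfinite(se) | (np.abs(b1) > SEPARATION_BOUND)
    beta = np.where(bad, np.nan, b1)
    se = np.where(bad, np.nan, se)
    return beta, se
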