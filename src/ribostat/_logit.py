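"""Newton solvers for weighted binomial and baseline-category multinomial
logistic regression with real-valued counts.

Counts enter the log-likelihood as weights, so fractional (normalized or
bias-corrected) counts are handled without rounding; the MLE for integer
counts coincides with the classic per-read Bernoulli fit because the
aggregated likelihoods are proportional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_ITER = 100
TOL = 1e-10
RIDGE = 1e-8


@dataclass
class LogitFit:
    """Result of one regression fit."""

    beta: np.ndarray          # (p,) binomial, or (S-1, p) multinomial
    se: np.ndarray            # same shape; NaN where the Hessian is singular
    loglik: float
    converged: bool
    separated: bool
    n_iter: int
    cov: np.ndarray | None = field(default=None, repr=False)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binomial_loglik(beta, X, successes, failures) -> float:
    eta = X @ beta
    # s*log(p) + f*log(1-p) = s*eta - (s+f)*log(1+e^eta)
    return float(successes @ eta - (successes + failures) @ np.logaddexp(0.0, eta))


def fit_binomial_logit(
    successes: np.ndarray,
    failures: np.ndarray,
    X: np.ndarray,
    separation_cap: float = 10.0,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogitFit:
    """MLE of a weighted binomial logit: logit P(success) = X beta.

    successes/failures are non-negative reals per observation (sample).
    """
    s = np.asarray(successes, dtype=float)
    f = np.asarray(failures, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll = binomial_loglik(beta, X, s, f)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        tot = s + f
        grad = X.T @ (s - tot * mu)
        w = tot * mu * (1 - mu)
        H = (X * w[:, None]).T @ X + RIDGE * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent
        new_ll = binomial_loglik(beta + step, X, s, f)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            halvings += 1
            if halvings > 30:
                break
            new_ll = binomial_loglik(beta + step, X, s, f)
        beta = beta + step
        if np.abs(step).max() < tol or abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    separated = bool(np.abs(beta).max() > separation_cap)
    eta = X @ beta
    mu = _sigmoid(eta)
    w = (s + f) * mu * (1 - mu)
    H = (X * w[:, None]).T @ X
    se = np.full(p, np.nan)
    cov = None
    try:
        cov = np.linalg.inv(H + RIDGE * np.eye(p))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        pass
    return LogitFit(beta, se, float(ll), converged, separated, it, cov)


# ---------------------------------------------------------------------------
# baseline-category multinomial
# ---------------------------------------------------------------------------

def _mn_probs(B: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Category probabilities; reference category appended last.

    B is (S-1, p); returns (n, S) with the reference as column S-1.
    """
    eta = X @ B.T                                    # (n, S-1)
    eta = np.column_stack([eta, np.zeros(len(X))])   # reference eta = 0
    eta -= eta.max(axis=1, keepdims=True)
    ez = np.exp(eta)
    return ez / ez.sum(axis=1, keepdims=True)


def multinomial_loglik(B: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Y is (n, S) counts with the REFERENCE category in the last column."""
    pi = _mn_probs(B, X)
    with np.errstate(divide="ignore"):
        lp = np.log(pi)
    lp[pi == 0] = 0.0  # only multiplied by zero counts in valid fits
    mask = Y > 0
    return float((Y[mask] * lp[mask]).sum())


def multinomial_null_loglik(Y: np.ndarray) -> float:
    """Intercept-only MLE log-likelihood: pooled category proportions."""
    tot = Y.sum()
    if tot == 0:
        return 0.0
    col = Y.sum(axis=0)
    pos = col > 0
    return float((col[pos] * np.log(col[pos] / tot)).sum())


def fit_multinomial_logit(
    Y: np.ndarray,
    X: np.ndarray,
    separation_cap: float = 10.0,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogitFit:
    """MLE of a baseline-category multinomial logit with real-valued counts.

    Y : (n, S) counts, reference category LAST; X : (n, p) design with
    intercept. Models log(pi_m / pi_ref) = X B_m for m = 1..S-1.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, S = Y.shape
    p = X.shape[1]
    m = S - 1
    B = np.zeros((m, p))
    ll = multinomial_loglik(B, X, Y)
    N = Y.sum(axis=1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = _mn_probs(B, X)                         # (n, S)
        resid = Y[:, :m] - N[:, None] * pi[:, :m]    # (n, m)
        grad = (resid.T @ X).ravel()                 # vec by category-major
        # Hessian blocks H[(a,b)] = sum_s N_s x x^T (pi_a δ_ab - pi_a pi_b)
        H = np.zeros((m * p, m * p))
        for a in range(m):
            for b in range(a, m):
                w = N * (pi[:, a] * ((a == b) - pi[:, b]))
                blk = (X * w[:, None]).T @ X
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
                if b != a:
                    H[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk
        H += RIDGE * np.eye(m * p)
        try:
            step = np.linalg.solve(H, grad).reshape(m, p)
        except np.linalg.LinAlgError:
            break
        new_ll = multinomial_loglik(B + step, X, Y)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            halvings += 1
            if halvings > 30:
                break
            new_ll = multinomial_loglik(B + step, X, Y)
        B = B + step
        if np.abs(step).max() < tol or abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    separated = bool(np.abs(B).max() > separation_cap)
    # observed information at the MLE for SEs
    pi = _mn_probs(B, X)
    H = np.zeros((m * p, m * p))
    for a in range(m):
        for b in range(a, m):
            w = N * (pi[:, a] * ((a == b) - pi[:, b]))
            blk = (X * w[:, None]).T @ X
            H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
            if b != a:
                H[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk
    se = np.full((m, p), np.nan)
    cov = None
    try:
        cov = np.linalg.inv(H + RIDGE * np.eye(m * p))
        se = np.sqrt(np.diag(cov)).reshape(m, p)
    except np.linalg.LinAlgError:
        pass
    return LogitFit(B, se, float(ll), converged, separated, it, cov)
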