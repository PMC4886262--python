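"""High-breakdown MM regression.

Two-stage robust linear regression: an S-estimator with a 50%-breakdown
bisquare M-scale provides the initial coefficients and the fixed residual
scale, followed by a redescending bisquare M-step tuned for 95% asymptotic
efficiency at the Gaussian model.  Standard errors come from the usual
asymptotic MM covariance.  Written here because the scientific Python stack
has no high-breakdown regression estimator (statsmodels' RLM is a monotone
M-estimator with re-estimated scale, which has breakdown point 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: bisquare tuning constant for the 50%-breakdown S stage
C_S = 1.547645
#: bisquare tuning constant for 95% Gaussian efficiency in the M stage
C_M = 4.685061
#: consistency constant: E[rho_c(Z)] = b at the standard normal, c = C_S
B_S = 0.5


def rho_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    """Bisquare rho normalized to max 1."""
    x = np.clip(u / c, -1.0, 1.0)
    return 1.0 - (1.0 - x ** 2) ** 3


def psi_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    out = np.zeros_like(u, dtype=float)
    m = np.abs(u) <= c
    t = u[m] / c
    out[m] = u[m] * (1.0 - t ** 2) ** 2
    return out


def psi_prime_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    out = np.zeros_like(u, dtype=float)
    m = np.abs(u) <= c
    t = (u[m] / c) ** 2
    out[m] = (1.0 - t) * (1.0 - 5.0 * t)
    return out


def weight_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    out = np.zeros_like(u, dtype=float)
    m = np.abs(u) <= c
    out[m] = (1.0 - (u[m] / c) ** 2) ** 2
    return out


def m_scale(resid: np.ndarray, c: float = C_S, b: float = B_S,
            s0: float | None = None, tol: float = 1e-9,
            max_iter: int = 200) -> float:
    """Solve mean(rho(r/s)) = b for s by fixed-point iteration."""
    r = np.asarray(resid, dtype=float)
    if np.all(r == 0):
        return 0.0
    s = s0 if s0 and s0 > 0 else np.median(np.abs(r)) / 0.6745
    if s <= 0:
        s = np.abs(r[r != 0]).mean()
    for _ in range(max_iter):
        m = rho_bisquare(r / s, c).mean()
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return s_new
        s = s_new
    return s


def _irls(X: np.ndarray, y: np.ndarray, beta: np.ndarray, scale: float,
          c: float, n_steps: int, tol: float = 1e-10) -> np.ndarray:
    """Fixed-scale bisquare IRLS refinement steps."""
    for _ in range(n_steps):
        r = y - X @ beta
        w = weight_bisquare(r / scale, c)
        if w.sum() <= X.shape[1]:
            break
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) <= tol * (
            1.0 + np.max(np.abs(beta))
        ):
            beta = beta_new
            break
        beta = beta_new
    return beta


@dataclass
class MMFit:
    """Result of an MM regression fit."""

    params: np.ndarray
    scale: float          # S-stage M-scale of the residuals
    cov_params: np.ndarray
    converged: bool
    s_params: np.ndarray  # initial S-stage coefficients

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def _s_estimator(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                 n_subsets: int, n_keep: int = 5
                 ) -> tuple[np.ndarray, float]:
    """Fast-S: elemental subsets, short refinements, full refinement of the best."""
    n, p = X.shape
    best: list[tuple[float, np.ndarray]] = []
    tries = 0
    while len(best) < n_subsets and tries < 20 * n_subsets:
        tries += 1
        idx = rng.choice(n, size=p, replace=False)
        try:
            beta = np.linalg.solve(X[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        r = y - X @ beta
        s = m_scale(r, C_S)
        if s == 0:  # exact fit of more than half the data
            return beta, 0.0
        beta = _irls(X, y, beta, s, C_S, n_steps=2)
        s = m_scale(y - X @ beta, C_S, s0=s)
        best.append((s, beta))
    if not best:
        raise np.linalg.LinAlgError("no non-singular elemental subset found")
    best.sort(key=lambda t: t[0])
    s_best, beta_best = np.inf, best[0][1]
    for s, beta in best[:n_keep]:
        for _ in range(50):
            beta_new = _irls(X, y, beta, s, C_S, n_steps=1)
            s_new = m_scale(y - X @ beta_new, C_S, s0=s)
            if abs(s_new - s) <= 1e-8 * s:
                beta, s = beta_new, s_new
                break
            beta, s = beta_new, s_new
        if s < s_best:
            s_best, beta_best = s, beta
    return beta_best, s_best


def fit_mm(X: np.ndarray, y: np.ndarray, seed: int = 0,
           n_subsets: int = 100) -> MMFit:
    """MM regression: S-stage scale + 95%-efficiency bisquare M-stage.

    The returned covariance is the asymptotic sandwich
    ``scale^2 * [n/(n-p)] * mean(psi^2) / mean(psi')^2 * (X'X)^{-1}``
    evaluated at the M-stage residuals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    rng = np.random.default_rng(seed)
    beta_s, scale = _s_estimator(X, y, rng, n_subsets)
    if scale == 0:
        cov = np.zeros((p, p))
        return MMFit(beta_s, 0.0, cov, True, beta_s)

    beta = beta_s.copy()
    converged = False
    for _ in range(200):
        beta_new = _irls(X, y, beta, scale, C_M, n_steps=1)
        if np.max(np.abs(beta_new - beta)) <= 1e-10 * (
            1.0 + np.max(np.abs(beta))
        ):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    # the M-step must not lose the S-step's robustness: keep whichever
    # coefficient vector has the smaller bisquare objective at fixed scale
    if rho_bisquare((y - X @ beta) / scale, C_M).sum() > rho_bisquare(
        (y - X @ beta_s) / scale, C_M
    ).sum():
        beta = beta_s

    u = (y - X @ beta) / scale
    a = np.mean(psi_bisquare(u, C_M) ** 2)
    b = np.mean(psi_prime_bisquare(u, C_M))
    if b <= 0:
        b = 1e-8
    kappa = (n / (n - p)) * a / (b ** 2)
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov = scale ** 2 * kappa * xtx_inv
    return MMFit(beta, scale, cov, converged, beta_s)
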