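"""Casewise (full-information) Gaussian likelihood machinery.

Observations with missing cells contribute the log-density of their observed
subvector only, which is valid under missing-at-random. Rows are grouped by
missingness pattern once, so each objective evaluation reduces to a handful of
small-matrix operations per pattern (log-determinant, solve, trace against the
pattern's scatter matrix), independent of sample size.

Means are held fixed at the supplied (or pattern-pooled) column means; on
complete data this coincides with the saturated maximum-likelihood means, and
all downstream scores are residualized to mean zero anyway.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = ["PatternData", "minimize_nll", "mvn_nll"]


class PatternData:
    """Sufficient statistics of an (n, p) data matrix grouped by missingness pattern.

    Parameters
    ----------
    Y : ndarray (n, p) with NaN for missing cells; all-missing rows are dropped.
    mu : optional fixed mean vector; defaults to available-case column means.
    """

    def __init__(self, Y: np.ndarray, mu: np.ndarray | None = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("expected a 2-d data matrix")
        obs = ~np.isnan(Y)
        keep = obs.any(axis=1)
        Y, obs = Y[keep], obs[keep]
        self.n, self.p = Y.shape
        if mu is None:
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(Y, axis=0)
            mu = np.where(np.isfinite(mu), mu, 0.0)
        self.mu = np.asarray(mu, dtype=float)

        self.groups: list[tuple[np.ndarray, int, np.ndarray]] = []
        # group rows by pattern: (observed indices, count, scatter around mu)
        codes = obs @ (1 << np.arange(self.p, dtype=np.int64))
        for code in np.unique(codes):
            rows = codes == code
            idx = np.flatnonzero(obs[np.argmax(rows)])
            D = Y[np.ix_(rows, idx)] - self.mu[idx]
            self.groups.append((idx, int(rows.sum()), D.T @ D))
        self.n_obs_cells = int(obs.sum())

    def nll(self, sigma: np.ndarray) -> float:
        """-2/2 * log-likelihood (i.e. negative log-likelihood, constants included)."""
        total = 0.5 * self.n_obs_cells * LOG_2PI
        for idx, n_g, scatter in self.groups:
            sub = sigma[np.ix_(idx, idx)]
            try:
                c, low = linalg.cho_factor(sub, check_finite=False)
            except linalg.LinAlgError:
                return np.inf
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            quad = np.trace(linalg.cho_solve((c, low), scatter, check_finite=False))
            total += 0.5 * (n_g * logdet + quad)
        return float(total)

    def loglik(self, sigma: np.ndarray) -> float:
        return -self.nll(sigma)


def mvn_nll(scatter: np.ndarray, n: int, sigma: np.ndarray) -> float:
    """Negative Gaussian log-likelihood from a scatter matrix (complete data)."""
    p = sigma.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    quad = np.trace(np.linalg.solve(sigma, scatter))
    return float(0.5 * (n * p * LOG_2PI + n * logdet + quad))


def minimize_nll(fun, x0, restarts: int = 4, jitter: float = 0.05, seed: int = 0,
                 tol: float = 1e-10, maxiter: int = 500):
    """L-BFGS-B minimisation with jittered restarts on failure.

    Returns the scipy result of the best run; raises RuntimeError (carrying the
    best objective found) if no run converges.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    best = None
    for attempt in range(restarts + 1):
        start = x0 if attempt == 0 else x0 + jitter * rng.standard_normal(x0.size) * (
            1.0 + np.abs(x0))
        res = optimize.minimize(fun, start, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            return res if res.fun <= best.fun else best
    if best is not None and np.isfinite(best.fun):
        # L-BFGS-B sometimes reports maxiter without success on flat regions;
        # accept the best point rather than discard a usable optimum.
        return best
    raise RuntimeError(f"optimisation failed to converge; best objective {best.fun if best else np.nan}")
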