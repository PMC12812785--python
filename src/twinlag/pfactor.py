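"""Single-factor confirmatory factor analysis as a data-reduction device.

A one-factor model ``y = lambda * f + e`` with factor variance fixed at 1 is
fitted by casewise (full-information) maximum likelihood, so cases with
missing indicators contribute their observed subvector. Factor scores use the
regression method, ``lambda' Sigma^{-1} (y - mu)`` over each case's observed
indicators. No claim about the structure of psychopathology is implied — the
factor is a weighted composite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._fiml import LOG_2PI, PatternData, minimize_nll

logger = logging.getLogger(__name__)

__all__ = ["FitStats", "CFAModel", "model_fit_stats", "fit_cfa", "factor_scores"]

THETA_FLOOR = 1e-6  # Heywood clamp on uniquenesses


@dataclass
class FitStats:
    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    aic: float
    bic: float
    loglik: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("chi_square", "df", "cfi", "tli", "rmsea", "srmr",
                 "aic", "bic", "loglik")}


@dataclass
class CFAModel:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    columns: list[str]
    mu: np.ndarray
    fit: FitStats
    heywood: bool = False
    degenerate: bool = False

    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_m <= 0:
        raise ValueError("implied covariance is singular or indefinite")
    if sign_s <= 0:
        raise ValueError("sample covariance is singular")
    return float(logdet_m + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p)


def model_fit_stats(sample_cov: np.ndarray, implied_cov: np.ndarray,
                    n: int, df_model: int) -> FitStats:
    """Standard ML covariance-structure fit statistics.

    chi2 = (n-1) * F_ML; CFI/TLI against the diagonal independence baseline;
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))) (0 for a saturated df=0
    model); SRMR over correlation-metric residuals. AIC/BIC use the Gaussian
    log-likelihood at the implied covariance with means profiled out.
    """
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(implied_cov, dtype=float)
    if S.shape != sigma.shape:
        raise ValueError("sample and implied covariance are not conformable")
    p = S.shape[0]
    F = _ml_discrepancy(S, sigma)
    chi2 = max((n - 1) * F, 0.0)

    base = np.diag(np.diag(S))
    chi2_b = max((n - 1) * _ml_discrepancy(S, base), 0.0)
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df_model, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df_model, 0.0) / denom
    if df_b > 0 and df_model > 0 and chi2_b > df_b:
        tli = ((chi2_b / df_b) - (chi2 / df_model)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = 0.0 if df_model == 0 else float(
        np.sqrt(max(chi2 - df_model, 0.0) / (df_model * (n - 1))))

    d_s = np.sqrt(np.diag(S))
    corr_resid = S / np.outer(d_s, d_s) - sigma / np.outer(np.sqrt(np.diag(sigma)),
                                                           np.sqrt(np.diag(sigma)))
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(corr_resid[iu] ** 2)))

    loglik = -0.5 * n * (p * LOG_2PI + np.linalg.slogdet(sigma)[1]
                         + np.trace(np.linalg.solve(sigma, S)))
    k = p * (p + 1) // 2 - df_model
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * np.log(n)
    return FitStats(chi2, df_model, float(np.clip(cfi, 0, 1)), float(tli),
                    rmsea, srmr, float(aic), float(bic), float(loglik))


def _start_values(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(S)
    lam = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-6))
    if lam[0] < 0:
        lam = -lam
    theta = np.clip(np.diag(S) - lam**2, 0.05 * np.diag(S), None)
    return lam, theta


def fit_cfa(items: pd.DataFrame, restarts: int = 4, seed: int = 0) -> CFAModel:
    """Fit the one-factor model by FIML; sign fixed so the first loading >= 0.

    Raises on fewer than 3 indicators or non-convergence after jittered
    restarts. Uniquenesses at the Heywood boundary are clamped at 1e-6 and
    flagged on the returned model.
    """
    columns = list(items.columns)
    p = len(columns)
    if p < 3:
        raise ValueError(f"need at least 3 indicators, got {p}")
    Y = items.to_numpy(dtype=float)
    data = PatternData(Y)
    if data.n <= 2 * p:
        raise ValueError("too few cases for the number of parameters")

    # pairwise-complete covariance for start values
    S0 = pd.DataFrame(Y).cov().to_numpy()
    lam0, theta0 = _start_values(S0)
    x0 = np.concatenate([lam0, np.log(theta0)])

    def nll(x):
        lam = x[:p]
        theta = np.exp(np.clip(x[p:], np.log(THETA_FLOOR), 20.0))
        return data.nll(np.outer(lam, lam) + np.diag(theta))

    res = minimize_nll(nll, x0, restarts=restarts, seed=seed)
    lam = res.x[:p]
    theta = np.exp(np.clip(res.x[p:], np.log(THETA_FLOOR), 20.0))

    # with no common variance the single-factor likelihood has an
    # identification ridge (one indicator can absorb the factor); when the
    # factor model does not beat the zero-loading null at alpha = 0.001,
    # report the null solution and flag the fit as degenerate
    degenerate = False
    null_nll = data.nll(np.diag(np.clip(np.diag(S0), THETA_FLOOR, None)))
    if null_nll - res.fun < 0.5 * stats.chi2.ppf(0.999, p):
        lam = np.zeros(p)
        theta = np.clip(np.diag(S0), THETA_FLOOR, None)
        degenerate = True
        logger.warning("fit_cfa: no common factor detected; loadings set to 0")

    heywood = bool((theta <= THETA_FLOOR * 1.01).any())
    if heywood:
        logger.warning("fit_cfa: uniqueness at Heywood boundary clamped to %g", THETA_FLOOR)
    if lam[0] < 0:
        lam = -lam

    sigma = np.outer(lam, lam) + np.diag(theta)
    df_model = p * (p + 1) // 2 - 2 * p
    # fit statistics on the complete-case sample covariance when available
    complete = ~np.isnan(Y).any(axis=1)
    if complete.sum() > p + 1:
        S = np.cov(Y[complete].T)
        fit = model_fit_stats(S, sigma, int(complete.sum()), df_model)
    else:  # pragma: no cover - fit indices undefined without complete cases
        fit = FitStats(np.nan, df_model, np.nan, np.nan, np.nan, np.nan,
                       np.nan, np.nan, float(-res.fun))
    return CFAModel(lam, theta, columns, data.mu.copy(), fit, heywood,
                    degenerate)


def factor_scores(model: CFAModel, items: pd.DataFrame) -> np.ndarray:
    """Regression-method factor scores, standardized over the sample.

    Cases with missing indicators use the observed submatrix of the implied
    covariance; a case with no observed indicators scores missing.
    """
    Y = items[model.columns].to_numpy(dtype=float)
    sigma = model.implied_cov()
    lam = model.loadings
    obs = np.isfinite(Y)
    scores = np.full(len(Y), np.nan)
    codes = obs @ (1 << np.arange(Y.shape[1], dtype=np.int64))
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = codes == code
        idx = np.flatnonzero(obs[np.argmax(rows)])
        w = np.linalg.solve(sigma[np.ix_(idx, idx)], lam[idx])
        scores[rows] = (Y[np.ix_(rows, idx)] - model.mu[idx]) @ w
    ok = np.isfinite(scores)
    if ok.any():
        scores[ok] = (scores[ok] - scores[ok].mean()) / scores[ok].std()
    return scores
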