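"""Bivariate three-wave cross-lagged panel model (CLPM).

Each wave's (P, H) pair is regressed on the immediately preceding wave only
(lag-1), with the wave-1 covariance and both innovation covariances free.
On complete data the likelihood factorizes across the recursive structure, so
the ML paths equal equation-wise least squares of wave t+1 on wave t; with
missing cells the casewise (FIML) likelihood is maximized numerically.
Standardized paths use model-implied SDs; cross-sectional parameters are
reported as correlations. Confidence intervals come from a case-resampling
percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fiml import PatternData, minimize_nll
from .pfactor import FitStats, model_fit_stats

__all__ = ["CLPMFit", "fit_clpm", "standardize_paths", "bootstrap_clpm",
           "simulate_clpm", "clpm_params_standardized", "CLPM_COLUMNS"]

CLPM_COLUMNS = ["P9", "H9", "P12", "H12", "P16", "H16"]
MODEL_DF = 4  # 21 saturated moments - 17 free parameters

#: standardized lagged path labels in reporting order
PATH_LABELS = [
    "P9->P12", "H9->P12", "P9->H12", "H9->H12",
    "P12->P16", "H12->P16", "P12->H16", "H12->H16",
]
CROSS_SECTIONAL_LABELS = ["P9~~H9", "P12~~H12", "P16~~H16"]


@dataclass
class CLPMFit:
    sigma1: np.ndarray
    B12: np.ndarray
    B23: np.ndarray
    psi2: np.ndarray
    psi3: np.ndarray
    paths: dict = field(default_factory=dict)       # standardized estimates
    ci: dict = field(default_factory=dict)          # label -> (lo, hi)
    fit: FitStats | None = None
    n_used: int = 0

    def implied_cov(self) -> np.ndarray:
        s1, B12, B23 = self.sigma1, self.B12, self.B23
        s2 = B12 @ s1 @ B12.T + self.psi2
        s3 = B23 @ s2 @ B23.T + self.psi3
        c21 = B12 @ s1
        c31 = B23 @ c21
        c32 = B23 @ s2
        out = np.zeros((6, 6))
        out[0:2, 0:2], out[2:4, 2:4], out[4:6, 4:6] = s1, s2, s3
        out[2:4, 0:2], out[4:6, 0:2], out[4:6, 2:4] = c21, c31, c32
        out[0:2, 2:4], out[0:2, 4:6], out[2:4, 4:6] = c21.T, c31.T, c32.T
        return out

    def raw_paths(self) -> dict:
        vals = {}
        for B, (pred, outw) in ((self.B12, (9, 12)), (self.B23, (12, 16))):
            for k, to in enumerate(("P", "H")):
                for j, frm in enumerate(("P", "H")):
                    vals[f"{frm}{pred}->{to}{outw}"] = float(B[k, j])
        return vals


def _params_to_mats(x: np.ndarray):
    def chol(v):
        L = np.array([[v[0], 0.0], [v[1], v[2]]])
        return L @ L.T
    sigma1 = chol(x[0:3])
    B12 = x[3:7].reshape(2, 2)
    psi2 = chol(x[7:10])
    B23 = x[10:14].reshape(2, 2)
    psi3 = chol(x[14:17])
    return sigma1, B12, psi2, B23, psi3


def _mats_to_params(sigma1, B12, psi2, B23, psi3) -> np.ndarray:
    def ichol(m):
        L = np.linalg.cholesky(m + 1e-10 * np.eye(2))
        return [L[0, 0], L[1, 0], L[1, 1]]
    return np.array(ichol(sigma1) + list(B12.ravel()) + ichol(psi2)
                    + list(B23.ravel()) + ichol(psi3))


def _implied(sigma1, B12, psi2, B23, psi3) -> np.ndarray:
    return CLPMFit(sigma1, B12, B23, psi2, psi3).implied_cov()


def _fit_complete(Y: np.ndarray):
    """Closed-form ML on complete data: equation-wise least squares."""
    S = np.cov(Y.T, bias=True)
    s1 = S[0:2, 0:2]
    B12 = S[2:4, 0:2] @ np.linalg.inv(s1)
    psi2 = S[2:4, 2:4] - B12 @ S[0:2, 2:4]
    s2 = S[2:4, 2:4]
    B23 = S[4:6, 2:4] @ np.linalg.inv(s2)
    psi3 = S[4:6, 4:6] - B23 @ S[2:4, 4:6]
    return s1, B12, psi2, B23, psi3


def _monotone_fit(Y: np.ndarray):
    """Exact ML under monotone wave dropout (e.g. wave-3 attrition).

    When every row observes a prefix of the waves (each wave all-or-none),
    the lag-1 likelihood factorizes into p(y1) p(y2|y1) p(y3|y2) with
    distinct parameters, so each factor is maximized by regression on its
    available subsample. Returns None when the pattern is not monotone.
    """
    wave_obs = np.stack([np.isfinite(Y[:, 2 * t:2 * t + 2]) for t in range(3)],
                        axis=1)  # (n, 3, 2)
    all_obs = wave_obs.all(axis=2)
    none_obs = ~wave_obs.any(axis=2)
    if not (all_obs | none_obs).all():
        return None  # cell-level missingness
    # monotone: observed waves form a prefix
    if not ((all_obs[:, 1] <= all_obs[:, 0]) & (all_obs[:, 2] <= all_obs[:, 1])).all():
        return None

    def regress(rows, pred, out):
        Z = Y[rows]
        Zc = Z - Z.mean(axis=0)
        X, R = Zc[:, pred], Zc[:, out]
        B = np.linalg.solve(X.T @ X, X.T @ R).T
        resid = R - X @ B.T
        return B, (resid.T @ resid) / len(Z)

    w1 = Y[all_obs[:, 0]][:, 0:2]
    s1 = np.cov(w1.T, bias=True)
    if all_obs[:, 1].sum() < 10 or all_obs[:, 2].sum() < 10:
        return None
    B12, psi2 = regress(all_obs[:, 1], [0, 1], [2, 3])
    B23, psi3 = regress(all_obs[:, 2], [2, 3], [4, 5])
    return s1, B12, psi2, B23, psi3


def fit_clpm(data: pd.DataFrame, compute_fit: bool = True,
             start: np.ndarray | None = None) -> CLPMFit:
    """ML fit of the lag-1 CLPM on a singleton wide table (columns P9..H16).

    ``start`` optionally warm-starts the FIML optimizer (used by the
    bootstrap); it is ignored on complete data where the fit is closed form.
    """
    Y = data[CLPM_COLUMNS].to_numpy(dtype=float)
    any_obs = np.isfinite(Y).any(axis=1)
    Y = Y[any_obs]
    if len(Y) < 50:
        raise ValueError(f"need >= 50 cases with any data, got {len(Y)}")

    complete = np.isfinite(Y).all(axis=1)
    if complete.all():
        s1, B12, psi2, B23, psi3 = _fit_complete(Y)
        S_sat = np.cov(Y.T, bias=True)
        n = len(Y)
    else:
        mono = _monotone_fit(Y)
        if mono is not None:
            s1, B12, psi2, B23, psi3 = mono
        else:
            data_f = PatternData(Y)
            if start is not None:
                x0 = start
            elif complete.sum() > 7:
                x0 = _mats_to_params(*_fit_complete(Y[complete]))
            else:
                x0 = _mats_to_params(np.eye(2), np.zeros((2, 2)), np.eye(2),
                                     np.zeros((2, 2)), np.eye(2))

            def nll(x):
                return data_f.nll(_implied(*_params_to_mats(x)))

            res = minimize_nll(nll, x0)
            s1, B12, psi2, B23, psi3 = _params_to_mats(res.x)
        S_sat = pd.DataFrame(Y).cov().to_numpy() if complete.sum() <= 7 \
            else np.cov(Y[complete].T, bias=True)
        n = len(Y)

    for name, m in (("wave-1 covariance", s1), ("wave-2 innovations", psi2)):
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError(f"rank-deficient predictors: singular {name}")

    fit = CLPMFit(s1, B12, B23, psi2, psi3, n_used=int(n))
    if compute_fit:
        fit.fit = model_fit_stats(S_sat, fit.implied_cov(), int(n), MODEL_DF)
    return standardize_paths(fit)


def standardize_paths(fit: CLPMFit) -> CLPMFit:
    """Populate standardized paths: beta = b * SD(predictor) / SD(outcome).

    Cross-sectional entries (wave-1 covariance, innovation covariances) are
    reported as correlations.
    """
    sigma = fit.implied_cov()
    sd = np.sqrt(np.diag(sigma))
    if (sd <= 0).any():
        raise ValueError("zero model-implied SD; cannot standardize")
    paths = {}
    for B, (pred_w, out_w), (pi, oi) in ((fit.B12, (9, 12), (0, 2)),
                                         (fit.B23, (12, 16), (2, 4))):
        for k, to in enumerate(("P", "H")):
            for j, frm in enumerate(("P", "H")):
                paths[f"{frm}{pred_w}->{to}{out_w}"] = float(
                    B[k, j] * sd[pi + j] / sd[oi + k])
    for label, m in zip(CROSS_SECTIONAL_LABELS, (fit.sigma1, fit.psi2, fit.psi3)):
        denom = np.sqrt(m[0, 0] * m[1, 1])
        paths[label] = float(m[0, 1] / denom) if denom > 0 else np.nan
    fit.paths = paths
    return fit


def bootstrap_clpm(data: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                   fit: CLPMFit | None = None) -> CLPMFit:
    """Percentile 95% CIs for every standardized path by case resampling."""
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if fit is None:
        fit = fit_clpm(data)
    rng = np.random.default_rng(seed)
    rows = data.reset_index(drop=True)
    warm = _mats_to_params(fit.sigma1, fit.B12, fit.psi2, fit.B23, fit.psi3)
    draws = {label: [] for label in fit.paths}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(rows), size=len(rows))
        try:
            bfit = fit_clpm(rows.iloc[idx], compute_fit=False, start=warm)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failures += 1
            if failures > 0.05 * n_boot:
                raise RuntimeError(
                    f"bootstrap failure rate exceeded 5% ({failures} of {n_boot})")
            continue
        for label, v in bfit.paths.items():
            draws[label].append(v)
    fit.ci = {label: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
              for label, v in draws.items()}
    return fit


# ---------------------------------------------------------------------------
# simulation helpers (singleton-level generator used for recovery runs)
# ---------------------------------------------------------------------------

def clpm_params_standardized(auto: tuple[float, float],
                             cross: dict[str, float],
                             r1: float = 0.3, innov_r: float = 0.2,
                             auto2: tuple[float, float] | None = None,
                             cross2: dict[str, float] | None = None):
    """Build raw CLPM matrices with unit variances at every wave.

    With all variables unit-variance the raw coefficients ARE the
    standardized paths. ``cross`` maps {"P->H": beta, "H->P": beta} for the
    9->12 transition; ``auto2``/``cross2`` override the 12->16 transition
    (defaulting to the first). Innovation variances are set to restore unit
    variance and innovation correlation ``innov_r``.
    """
    def trans(a, c):
        return np.array([[a[0], c.get("H->P", 0.0)],
                         [c.get("P->H", 0.0), a[1]]])

    sigma1 = np.array([[1.0, r1], [r1, 1.0]])
    B12 = trans(auto, cross)
    B23 = trans(auto2 or auto, cross2 if cross2 is not None else cross)

    def innov(B, s_prev):
        explained = B @ s_prev @ B.T
        d = 1.0 - np.diag(explained)
        if (d <= 0).any():
            raise ValueError("paths imply explained variance >= 1")
        psi = np.diag(d)
        off = innov_r * np.sqrt(d[0] * d[1])
        psi[0, 1] = psi[1, 0] = off
        if np.linalg.eigvalsh(psi).min() < 0:
            raise ValueError("innovation correlation infeasible")
        return psi

    psi2 = innov(B12, sigma1)
    s2 = B12 @ sigma1 @ B12.T + psi2
    psi3 = innov(B23, s2)
    return sigma1, B12, psi2, B23, psi3


def simulate_clpm(params, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw n singletons from a CLPM (params as from clpm_params_standardized)."""
    if n <= 0:
        raise ValueError("n must be positive")
    sigma = _implied(*params)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma + 1e-12 * np.eye(6))
    Y = rng.standard_normal((n, 6)) @ L.T
    return pd.DataFrame(Y, columns=CLPM_COLUMNS)
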