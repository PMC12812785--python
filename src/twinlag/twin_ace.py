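"""Twin ACE modelling: univariate variance decomposition and the biometric
autoregressive cross-lagged ACE model.

The univariate model decomposes one trait's variance into additive genetic
(A), shared environmental (C) and nonshared environmental (E) parts from the
MZ/DZ contrast in co-twin covariances. The cross-lagged model fits one latent
lag-1 process per component across two traits and three occasions to the full
12-dimensional pair observation, pooling MZ and DZ likelihoods; the fitted
component transitions are then turned into the percentage of each phenotypic
stability and cross-lagged path explained by A, C and E, and into the A/C/E
split of each wave's innovation ("unique") variance.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._fiml import PatternData, minimize_nll
from .cohort import (COMPONENTS, CROSS_TWIN_R, TRAITS, WAVES, ComponentProcess,
                     GenSpec, path_contributions)
from .pfactor import FitStats
from .preprocess import PAIR_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "ACEEstimate", "BiometricFit", "twin_correlations", "falconer_estimates",
    "fit_univariate_ace", "fit_crosslag_ace", "decompose_paths",
    "unique_variance", "compare_submodels",
]

#: decomposition rows in reporting order: (from_trait, to_trait, transition)
DECOMPOSITION_PATHS = [
    ("P", "P", "12"), ("P", "P", "23"),
    ("H", "H", "12"), ("H", "H", "23"),
    ("P", "H", "12"), ("P", "H", "23"),
    ("H", "P", "12"), ("H", "P", "23"),
]


@dataclass
class ACEEstimate:
    a2: float
    c2: float
    e2: float
    ci: dict = field(default_factory=dict)    # component -> (lo, hi)
    r_mz: float = np.nan
    r_dz: float = np.nan
    submodels: pd.DataFrame | None = None
    minus2ll: float = np.nan
    flags: list = field(default_factory=list)


@dataclass
class BiometricFit:
    processes: dict[str, ComponentProcess]
    fit: FitStats | None = None
    decomposition: pd.DataFrame | None = None
    innovation_shares: pd.DataFrame | None = None
    minus2ll: float = np.nan
    n_pairs: int = 0

    def phenotypic_paths(self) -> dict:
        """Model-implied standardized phenotypic lag-1 paths."""
        from .cohort import phenotypic_wave_covs
        spec_like = _SpecView(self.processes)
        covs = phenotypic_wave_covs(spec_like)
        out = {}
        for trans, (t_pred, t_out), waves in (("12", (0, 1), (9, 12)),
                                              ("23", (1, 2), (12, 16))):
            contrib, _ = path_contributions(self.processes, trans)
            B_ph = sum(contrib[x] for x in COMPONENTS)
            sd_pred = np.sqrt(np.diag(covs[t_pred]))
            sd_out = np.sqrt(np.diag(covs[t_out]))
            for k, to in enumerate(TRAITS):
                for j, frm in enumerate(TRAITS):
                    out[f"{frm}{waves[0]}->{to}{waves[1]}"] = float(
                        B_ph[k, j] * sd_pred[j] / sd_out[k])
        return out


class _SpecView:
    """Duck-typed stand-in exposing .processes for spec-level helpers."""

    def __init__(self, processes):
        self.processes = processes


# ---------------------------------------------------------------------------
# twin correlations and Falconer arithmetic
# ---------------------------------------------------------------------------

def _pair_values(pairs: pd.DataFrame, trait: str, wave: int) -> np.ndarray:
    cols = [f"{trait}{wave}_1", f"{trait}{wave}_2"]
    return pairs[cols].to_numpy(dtype=float)


def twin_correlations(pairs: pd.DataFrame, trait: str, wave: int,
                      min_pairs: int = 30) -> tuple[float, float]:
    """Double-entered Pearson co-twin correlation per zygosity.

    ``pairs`` is the wide one-row-per-pair table (see preprocess.pair_wide).
    Each complete pair contributes both orderings, the standard way of making
    the correlation invariant to twin labelling.
    """
    out = []
    for code in ("MZ", "DZ"):
        v = _pair_values(pairs[pairs["zygosity"] == code], trait, wave)
        v = v[np.isfinite(v).all(axis=1)]
        if len(v) < min_pairs:
            raise ValueError(
                f"only {len(v)} complete {code} pairs for {trait}{wave}; need {min_pairs}")
        x = np.concatenate([v[:, 0], v[:, 1]])
        y = np.concatenate([v[:, 1], v[:, 0]])
        out.append(float(np.corrcoef(x, y)[0, 1]))
    return tuple(out)


def falconer_estimates(r_mz: float, r_dz: float):
    """Closed-form ACE fractions: a2 = 2(rMZ - rDZ), c2 = rMZ - a2, e2 = 1 - rMZ.

    Out-of-bound components are flagged, not clamped. Returns
    ((a2, c2, e2), flags).
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    flags = [f"{name} out of [0, 1]" for name, v in
             (("a2", a2), ("c2", c2), ("e2", e2)) if not 0.0 <= v <= 1.0]
    return (a2, c2, e2), flags


# ---------------------------------------------------------------------------
# univariate ACE maximum likelihood
# ---------------------------------------------------------------------------

def _uni_sigma(x: np.ndarray, r_a: float) -> np.ndarray:
    a2, c2, e2 = x[0] ** 2, x[1] ** 2, x[2] ** 2
    v = a2 + c2 + e2
    cross = r_a * a2 + c2
    return np.array([[v, cross], [cross, v]])


_UNI_MODELS = {"ACE": (), "AE": (1,), "CE": (0,), "E": (0, 1)}


def _fit_uni(mz: PatternData, dz: PatternData, model: str = "ACE"):
    """Minimize the pooled FIML deviance over (a, c, e) square roots."""
    fixed = _UNI_MODELS[model]
    free = [i for i in range(3) if i not in fixed]
    x0_full = np.array([0.5, 0.4, 0.6])

    def expand(xf):
        x = np.zeros(3)
        x[free] = xf
        return x

    def nll(xf):
        x = expand(xf)
        return mz.nll(_uni_sigma(x, 1.0)) + dz.nll(_uni_sigma(x, 0.5))

    res = minimize_nll(nll, x0_full[free], restarts=4)
    x = expand(res.x)
    return x ** 2, float(res.fun)


def fit_univariate_ace(pairs: pd.DataFrame, trait: str, wave: int,
                       n_boot: int = 500, seed: int = 0,
                       submodels: bool = True) -> ACEEstimate:
    """FIML univariate ACE fit for one trait at one wave.

    Expected covariance per zygosity is [[V, r_A a2 + c2], [., V]] with
    V = a2 + c2 + e2; co-twin singletons contribute their marginal density.
    Fractions are reported relative to the fitted total V. CIs are pair-level
    percentile bootstrap (skipped when ``n_boot`` is 0).
    """
    groups = {}
    for code in ("MZ", "DZ"):
        v = _pair_values(pairs[pairs["zygosity"] == code], trait, wave)
        v = v[np.isfinite(v).any(axis=1)]
        if len(v) == 0:
            raise ValueError(f"no {code} pairs with data for {trait}{wave}")
        groups[code] = v
    mu = float(np.nanmean(np.concatenate([groups["MZ"].ravel(), groups["DZ"].ravel()])))
    mz = PatternData(groups["MZ"], mu=np.array([mu, mu]))
    dz = PatternData(groups["DZ"], mu=np.array([mu, mu]))

    (a2, c2, e2), m2ll_ace = (lambda r: (r[0], 2.0 * r[1]))(_fit_uni(mz, dz, "ACE"))
    total = a2 + c2 + e2
    est = ACEEstimate(a2 / total, c2 / total, e2 / total, minus2ll=m2ll_ace)
    try:
        est.r_mz, est.r_dz = twin_correlations(pairs, trait, wave)
    except ValueError:
        pass

    if submodels:
        rows = [{"model": "ACE", "minus2ll": m2ll_ace, "n_params": 3,
                 "aic": m2ll_ace + 6.0, "lrt_chi2": 0.0, "lrt_df": 0, "lrt_p": 1.0}]
        for name in ("AE", "CE", "E"):
            _, m2ll = (lambda r: (r[0], 2.0 * r[1]))(_fit_uni(mz, dz, name))
            k = 3 - len(_UNI_MODELS[name])
            lrt = max(m2ll - m2ll_ace, 0.0)
            df = len(_UNI_MODELS[name])
            rows.append({"model": name, "minus2ll": m2ll, "n_params": k,
                         "aic": m2ll + 2.0 * k, "lrt_chi2": lrt, "lrt_df": df,
                         "lrt_p": float(stats.chi2.sf(lrt, df))})
        est.submodels = pd.DataFrame(rows)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sub = pairs[[f"{trait}{wave}_1", f"{trait}{wave}_2", "zygosity"]]
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(sub), size=len(sub))
            bs = sub.iloc[idx]
            try:
                b = fit_univariate_ace(bs, trait, wave, n_boot=0, submodels=False)
            except (ValueError, RuntimeError):
                continue
            draws.append((b.a2, b.c2, b.e2))
        draws = np.array(draws)
        if len(draws):
            est.ci = {name: (float(np.percentile(draws[:, i], 2.5)),
                             float(np.percentile(draws[:, i], 97.5)))
                      for i, name in enumerate(("a2", "c2", "e2"))}
    return est


def compare_submodels(pairs: pd.DataFrame, trait: str, wave: int,
                      family=("ACE", "AE", "CE", "E")) -> pd.DataFrame:
    """Submodel comparison table (-2lnL, AIC, LRT vs the full ACE model)."""
    unknown = set(family) - set(_UNI_MODELS)
    if unknown:
        raise ValueError(f"unknown submodels: {sorted(unknown)}")
    if "ACE" not in family:
        raise ValueError("family must include the full ACE model for nesting")
    est = fit_univariate_ace(pairs, trait, wave, n_boot=0, submodels=True)
    return est.submodels[est.submodels["model"].isin(family)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# biometric cross-lagged ACE model
# ---------------------------------------------------------------------------

_N_PER_COMP = 17  # 3 chol(sigma1) + 4 B12 + 4 B23 + 3 chol(psi2) + 3 chol(psi3)


def _chol_vec_to_cov(v) -> np.ndarray:
    L = np.array([[v[0], 0.0], [v[1], v[2]]])
    return L @ L.T


def _cov_to_chol_vec(m) -> list[float]:
    w, V = np.linalg.eigh(0.5 * (m + m.T))
    m_psd = (V * np.clip(w, 1e-8, None)) @ V.T
    L = np.linalg.cholesky(m_psd)
    return [L[0, 0], L[1, 0], L[1, 1]]


def _x_to_mats(x: np.ndarray):
    """Unpack the 51-vector into per-component (sigma1, B12, B23, psi2, psi3)."""
    out = []
    for i in range(3):
        v = x[i * _N_PER_COMP:(i + 1) * _N_PER_COMP]
        out.append((_chol_vec_to_cov(v[0:3]), v[3:7].reshape(2, 2),
                    v[7:11].reshape(2, 2), _chol_vec_to_cov(v[11:14]),
                    _chol_vec_to_cov(v[14:17])))
    return out


def _within_block_mats(mats) -> np.ndarray:
    """Validation-free within-person 6x6 block (optimizer hot path)."""
    s1, B12, B23, psi2, psi3 = mats
    s2 = B12 @ s1 @ B12.T + psi2
    s3 = B23 @ s2 @ B23.T + psi3
    c21 = B12 @ s1
    c31 = B23 @ c21
    c32 = B23 @ s2
    out = np.empty((6, 6))
    out[0:2, 0:2], out[2:4, 2:4], out[4:6, 4:6] = s1, s2, s3
    out[2:4, 0:2], out[4:6, 0:2], out[4:6, 2:4] = c21, c31, c32
    out[0:2, 2:4], out[0:2, 4:6], out[2:4, 4:6] = c21.T, c31.T, c32.T
    return out


def _x_to_processes(x: np.ndarray) -> dict[str, ComponentProcess]:
    return {comp: ComponentProcess(comp, *mats)
            for comp, mats in zip(COMPONENTS, _x_to_mats(x))}


def _processes_to_x(procs: dict[str, ComponentProcess]) -> np.ndarray:
    x = []
    for comp in COMPONENTS:
        p = procs[comp]
        x += (_cov_to_chol_vec(p.sigma1) + list(p.B12.ravel()) + list(p.B23.ravel())
              + _cov_to_chol_vec(p.psi2) + _cov_to_chol_vec(p.psi3))
    return np.array(x)


def _expected_pair_cov(procs: dict[str, ComponentProcess], zygosity: str) -> np.ndarray:
    within = np.zeros((6, 6))
    cross = np.zeros((6, 6))
    for xc in COMPONENTS:
        w = procs[xc].within_block()
        within += w
        cross += CROSS_TWIN_R[zygosity][xc] * w
    return np.block([[within, cross], [cross, within]])


def _moment_start(mz_cov: np.ndarray, dz_cov: np.ndarray) -> dict[str, ComponentProcess]:
    """Consistent moment-based start values from sample pair covariances.

    The within block W and the MZ/DZ cross blocks identify each component's
    6x6 within-person covariance linearly: W_A = 2(C_MZ - C_DZ),
    W_C = 2 C_DZ - C_MZ, W_E = W - C_MZ. Each W_X is projected to the PSD cone
    and converted to lag-1 process parameters by block regression.
    """
    def blocks(cov):
        w = 0.5 * (cov[:6, :6] + cov[6:, 6:])
        c = 0.5 * (cov[:6, 6:] + cov[6:, :6].T)
        return w, 0.5 * (c + c.T)

    w_mz, c_mz = blocks(mz_cov)
    w_dz, c_dz = blocks(dz_cov)
    W = 0.5 * (w_mz + w_dz)
    W_X = {"A": 2.0 * (c_mz - c_dz), "C": 2.0 * c_dz - c_mz, "E": W - c_mz}

    procs = {}
    for comp, wx in W_X.items():
        vals, vecs = np.linalg.eigh(0.5 * (wx + wx.T))
        wx = (vecs * np.clip(vals, 1e-4, None)) @ vecs.T
        s1 = wx[0:2, 0:2]
        B12 = wx[2:4, 0:2] @ np.linalg.inv(s1)
        psi2 = wx[2:4, 2:4] - B12 @ wx[0:2, 2:4]
        s2 = wx[2:4, 2:4]
        B23 = wx[4:6, 2:4] @ np.linalg.inv(s2)
        psi3 = wx[4:6, 4:6] - B23 @ wx[2:4, 4:6]

        def psd(m):
            vv, ee = np.linalg.eigh(0.5 * (m + m.T))
            return (ee * np.clip(vv, 1e-4, None)) @ ee.T

        procs[comp] = ComponentProcess(comp, psd(s1), B12, B23, psd(psi2), psd(psi3))
    return procs


def _standardize_processes(procs: dict[str, ComponentProcess]) -> dict[str, ComponentProcess]:
    """Rescale so total phenotypic variance is 1 per trait per wave.

    Path-share decompositions are invariant to this rescaling; it only makes
    the reported component covariances and transitions comparable across
    waves.
    """
    wave_covs = {x: procs[x].wave_covs() for x in COMPONENTS}
    d = [np.sqrt(np.diag(sum(wave_covs[x][t] for x in COMPONENTS))) for t in range(3)]
    D = [np.diag(1.0 / dt) for dt in d]
    out = {}
    for x in COMPONENTS:
        p = procs[x]
        out[x] = ComponentProcess(
            x,
            D[0] @ p.sigma1 @ D[0],
            D[1] @ p.B12 @ np.diag(d[0]),
            D[2] @ p.B23 @ np.diag(d[1]),
            D[1] @ p.psi2 @ D[1],
            D[2] @ p.psi3 @ D[2],
        )
    return out


def fit_crosslag_ace(pairs: pd.DataFrame, restarts: int = 4,
                     standardize: bool = True) -> BiometricFit:
    """FIML fit of the component-level cross-lagged ACE model.

    Maximizes the pooled casewise Gaussian log-likelihood of the
    12-dimensional pair observation over MZ and DZ groups, with expected
    covariances built from the candidate A/C/E processes. Start values come
    from the moment decomposition of the sample pair covariances; the
    optimizer runs with up to ``restarts`` jittered restarts.
    """
    Y = {code: pairs.loc[pairs["zygosity"] == code, PAIR_COLUMNS].to_numpy(dtype=float)
         for code in ("MZ", "DZ")}
    for code, arr in Y.items():
        if not np.isfinite(arr).any():
            raise ValueError(f"no {code} pairs with data")
    # fixed pooled means per trait-wave, symmetric across co-twins
    col_means = np.nanmean(np.vstack([np.vstack(list(Y.values()))[:, :6],
                                      np.vstack(list(Y.values()))[:, 6:]]), axis=0)
    mu = np.concatenate([col_means, col_means])
    data = {code: PatternData(arr, mu=mu) for code, arr in Y.items()}

    def sample_cov(arr):
        ok = np.isfinite(arr).all(axis=1)
        if ok.sum() > 13:
            return np.cov(arr[ok].T, bias=True)
        return pd.DataFrame(arr).cov().to_numpy()

    x0 = _processes_to_x(_moment_start(sample_cov(Y["MZ"]), sample_cov(Y["DZ"])))

    r_a = {"MZ": 1.0, "DZ": 0.5}

    def nll(x):
        mats = _x_to_mats(x)
        w_blocks = [_within_block_mats(m) for m in mats]
        within = w_blocks[0] + w_blocks[1] + w_blocks[2]
        total = 0.0
        for code in ("MZ", "DZ"):
            cross = r_a[code] * w_blocks[0] + w_blocks[1]
            total += data[code].nll(np.block([[within, cross], [cross, within]]))
        return total

    res = minimize_nll(nll, x0, restarts=restarts)
    procs = _x_to_processes(res.x)
    if standardize:
        procs = _standardize_processes(procs)

    fit = BiometricFit(procs, minus2ll=2.0 * float(res.fun),
                       n_pairs=int(sum(d.n for d in data.values())))
    fit.decomposition = decompose_paths(fit)
    fit.innovation_shares = unique_variance(fit)

    # chi-square against the per-zygosity saturated covariances (complete pairs)
    from .pfactor import model_fit_stats
    try:
        chi2 = 0.0
        for code in ("MZ", "DZ"):
            arr = Y[code]
            ok = np.isfinite(arr).all(axis=1)
            if ok.sum() <= 13:
                raise ValueError
            fs = model_fit_stats(np.cov(arr[ok].T, bias=True),
                                 _expected_pair_cov(procs, code),
                                 int(ok.sum()), 1)
            chi2 += fs.chi_square
        df = 2 * 78 - 3 * _N_PER_COMP
        fit.fit = FitStats(chi2, df, np.nan, np.nan,
                           float(np.sqrt(max(chi2 - df, 0) / (df * (fit.n_pairs - 1)))),
                           np.nan, 2.0 * res.fun + 2 * 3 * _N_PER_COMP,
                           2.0 * res.fun + 3 * _N_PER_COMP * np.log(fit.n_pairs),
                           -float(res.fun))
    except ValueError:
        fit.fit = None
    return fit


def decompose_paths(fit) -> pd.DataFrame:
    """%A/%C/%E of every stability and cross-lagged phenotypic path.

    Component contributions are additive on the raw path scale. Percentages
    are contribution/path when all contributions share the path's sign;
    with mixed signs they are normalized by the sum of absolute
    contributions, which keeps every row nonnegative and summing to 100.
    """
    procs = fit.processes if hasattr(fit, "processes") else fit
    contribs = {trans: path_contributions(procs, trans)[0] for trans in ("12", "23")}
    rows = []
    for frm, to, trans in DECOMPOSITION_PATHS:
        j, k = TRAITS.index(frm), TRAITS.index(to)
        raw = np.array([contribs[trans][x][k, j] for x in COMPONENTS])
        total = raw.sum()
        signs = np.sign(raw[np.abs(raw) > 1e-12])
        mixed = len(set(signs)) > 1
        if np.abs(raw).sum() < 1e-12:
            pct = np.full(3, np.nan)
        elif mixed or total == 0:
            pct = 100.0 * np.abs(raw) / np.abs(raw).sum()
        else:
            pct = 100.0 * raw / total
        waves = (9, 12) if trans == "12" else (12, 16)
        rows.append({
            "path": f"{frm}{waves[0]}->{to}{waves[1]}",
            "phenotypic": total,
            "pct_A": pct[0], "pct_C": pct[1], "pct_E": pct[2],
            "raw_A": raw[0], "raw_C": raw[1], "raw_E": raw[2],
            "mixed_signs": bool(mixed),
        })
    return pd.DataFrame(rows)


def unique_variance(fit) -> pd.DataFrame:
    """A/C/E shares of each wave's innovation variance per trait.

    Wave 1 reports the initial variance decomposition; waves 2 and 3 the
    decomposition of the innovation (variance not transmitted from earlier
    occasions). All-zero innovations are reported as missing and flagged.
    """
    procs = fit.processes if hasattr(fit, "processes") else fit
    mats = {1: {x: procs[x].sigma1 for x in COMPONENTS},
            2: {x: procs[x].psi2 for x in COMPONENTS},
            3: {x: procs[x].psi3 for x in COMPONENTS}}
    rows = []
    for t, wave in enumerate(WAVES, start=1):
        for k, trait in enumerate(TRAITS):
            var = np.array([mats[t][x][k, k] for x in COMPONENTS])
            total = var.sum()
            if total < 1e-12:
                pct = np.full(3, np.nan)
                flag = "zero innovation variance"
            else:
                pct = 100.0 * var / total
                flag = ""
            rows.append({"wave": wave, "trait": trait, "total": total,
                         "pct_A": pct[0], "pct_C": pct[1], "pct_E": pct[2],
                         "flag": flag})
    return pd.DataFrame(rows)
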