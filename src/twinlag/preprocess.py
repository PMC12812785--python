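"""Data preparation: sex-difference descriptives, age/sex residualization,
one-twin-per-pair selection, and the home-environment composite.

All downstream analyses run on age- and sex-corrected standardized residuals
(mean 0, SD 1 over non-missing cases). Residualization pools both members of
each pair when estimating the nuisance regression coefficients; the (mildly
anticonservative) standard errors of these regressions are never used.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .cohort import MEASURE_COLUMNS, WAVES

logger = logging.getLogger(__name__)

__all__ = [
    "residualize_age_sex", "sex_eta_squared", "select_one_per_pair",
    "home_composite", "descriptives", "analysis_frame", "pair_wide",
]

_WAVE_RE = re.compile(r"_(\d+)$")


def _wave_of(column: str) -> int:
    if column.startswith("item_"):
        # item_<rater>_<wave>_<k>
        parts = column.split("_")
        if len(parts) == 4 and parts[2].isdigit() and int(parts[2]) in WAVES:
            return int(parts[2])
    else:
        m = _WAVE_RE.search(column)
        if m and int(m.group(1)) in WAVES:
            return int(m.group(1))
    raise ValueError(f"cannot infer wave from column {column!r}")


def _measure_columns(cohort: pd.DataFrame) -> list[str]:
    cols = [c for c in cohort.columns
            if c in MEASURE_COLUMNS or c.startswith("item_")]
    return [c for c in cols if cohort[c].notna().any()]


def residualize_age_sex(cohort: pd.DataFrame, columns: list[str] | None = None
                        ) -> pd.DataFrame:
    """Replace each measure by its z-scored OLS residual on age and sex.

    Per column, the regression uses the age at that column's wave and a 0/1
    female indicator plus an intercept, over non-missing rows; missing cells
    stay missing. Raises if a requested column has fewer than 3 observations.
    """
    out = cohort.copy()
    if columns is None:
        columns = _measure_columns(cohort)
    sex = (cohort["sex"] == "F").to_numpy(dtype=float)
    for col in columns:
        wave = _wave_of(col)
        y = cohort[col].to_numpy(dtype=float)
        age = cohort[f"age_{wave}"].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(age)
        if ok.sum() < 3:
            raise ValueError(f"column {col!r} has fewer than 3 non-missing values")
        X = np.column_stack([np.ones(ok.sum()), age[ok], sex[ok]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ beta
        sd = resid.std()
        if sd == 0:
            raise ValueError(f"column {col!r} is constant after residualization")
        z = np.full_like(y, np.nan)
        z[ok] = (resid - resid.mean()) / sd
        out[col] = z
    return out


def sex_eta_squared(values, sex) -> float:
    """One-way ANOVA effect size: between-group SS / total SS, in [0, 1]."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    ok = np.isfinite(values)
    values, sex = values[ok], sex[ok]
    groups = [values[sex == g] for g in pd.unique(sex)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("sex_eta_squared requires two nonempty groups")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = ((values - grand) ** 2).sum()
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def select_one_per_pair(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one random member of each pair (deterministic given the seed)."""
    rng = np.random.default_rng(seed)
    pairs = cohort["pair_id"].unique()
    pick = pd.Series(rng.integers(1, 3, size=len(pairs)), index=pairs)
    keep = cohort["twin"].to_numpy() == pick.loc[cohort["pair_id"]].to_numpy()
    return cohort[keep].reset_index(drop=True)


def home_composite(chaos, disc) -> np.ndarray:
    """Mean of the two standardized home indicators, re-standardized.

    If exactly one indicator is missing the observed one is carried through
    (a sample-preserving fallback, logged); both missing yields missing.
    """
    chaos = np.asarray(chaos, dtype=float)
    disc = np.asarray(disc, dtype=float)
    if chaos.shape != disc.shape:
        raise ValueError("chaos and discipline vectors differ in length")
    both = np.isfinite(chaos) & np.isfinite(disc)
    comp = np.where(both, 0.5 * (chaos + disc),
                    np.where(np.isfinite(chaos), chaos, disc))
    n_single = int((np.isfinite(chaos) ^ np.isfinite(disc)).sum())
    if n_single:
        logger.info("home_composite: %d cases used a single observed indicator", n_single)
    ok = np.isfinite(comp)
    comp[ok] = (comp[ok] - comp[ok].mean()) / comp[ok].std()
    return comp


def descriptives(cohort: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Mean/SD overall and by sex, plus the sex eta-squared, per measure."""
    if columns is None:
        columns = _measure_columns(cohort)
    sex = cohort["sex"].to_numpy()
    rows = []
    for col in columns:
        v = cohort[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        row = {"measure": col, "n": int(ok.sum()),
               "mean": np.nanmean(v), "sd": np.nanstd(v, ddof=1)}
        for g, label in (("F", "female"), ("M", "male")):
            gv = v[ok & (sex == g)]
            row[f"mean_{label}"] = gv.mean() if len(gv) else np.nan
            row[f"sd_{label}"] = gv.std(ddof=1) if len(gv) > 1 else np.nan
        try:
            row["sex_eta2"] = sex_eta_squared(v, sex)
        except ValueError:
            row["sex_eta2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def analysis_frame(cohort: pd.DataFrame, rater: str = "twin",
                   home: str = "composite", residualize: bool = True) -> pd.DataFrame:
    """Assemble the per-twin analysis table with columns P9..H16.

    P<wave> is the rater's p score; H<wave> is the home-environment composite
    (or a single indicator when ``home`` is "chaos"/"disc"). Input measures
    are age/sex-residualized first unless ``residualize`` is False.
    """
    p_cols = [f"p_{rater}_{w}" for w in WAVES]
    home_cols = {"composite": None, "chaos": [f"chaos_{w}" for w in WAVES],
                 "disc": [f"disc_{w}" for w in WAVES]}
    if home not in home_cols:
        raise ValueError("home must be 'composite', 'chaos' or 'disc'")
    need = p_cols + [f"chaos_{w}" for w in WAVES] + [f"disc_{w}" for w in WAVES]
    if residualize:
        cohort = residualize_age_sex(cohort, [c for c in need if cohort[c].notna().any()])
    out = cohort[["pair_id", "zygosity", "twin", "sex"]].copy()
    for w, p_col in zip(WAVES, p_cols):
        out[f"P{w}"] = cohort[p_col].to_numpy(dtype=float)
        if home == "composite":
            out[f"H{w}"] = home_composite(cohort[f"chaos_{w}"], cohort[f"disc_{w}"])
        else:
            out[f"H{w}"] = cohort[home_cols[home][WAVES.index(w)]].to_numpy(dtype=float)
    return out


#: column order of the paired 12-variable observation (twin1 then twin2)
PAIR_COLUMNS = [f"{t}{w}_{i}" for i in (1, 2) for w in WAVES for t in ("P", "H")]


def pair_wide(frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot the per-twin analysis table to one row per pair (12 trait columns)."""
    value_cols = [f"{t}{w}" for w in WAVES for t in ("P", "H")]
    wide = frame.pivot(index="pair_id", columns="twin", values=value_cols)
    wide.columns = [f"{v}_{t}" for v, t in wide.columns]
    zyg = frame.groupby("pair_id")["zygosity"].first()
    wide["zygosity"] = zyg
    for col in PAIR_COLUMNS:
        if col not in wide.columns:
            wide[col] = np.nan
    return wide[PAIR_COLUMNS + ["zygosity"]].reset_index()
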