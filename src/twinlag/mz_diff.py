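"""MZ-differences design: within-pair difference scores and their dynamics.

Because identical co-twins share all additive genetic and shared
environmental influences, the within-pair difference score cancels the A and
C processes exactly and follows the nonshared-environment (E) process alone.
Descriptives of the differences, their cross-wave correlations, and a CLPM
fitted to them therefore estimate E-specific dynamics: the standardized paths
of the difference-score CLPM converge to the standardized E-process
transitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clpm import CLPM_COLUMNS, CLPMFit, bootstrap_clpm, fit_clpm
from .cohort import WAVES

__all__ = ["mz_differences", "diff_correlations", "fit_diff_clpm"]


def mz_differences(frame: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Within-pair difference scores for MZ pairs, twin order randomized.

    ``frame`` is the per-twin analysis table (columns P9..H16 plus pair_id,
    twin, zygosity). DZ pairs are excluded; the sign of each pair's
    difference is randomized by the seeded stream; a difference is missing
    whenever either member is missing at that cell.
    """
    mz = frame[frame["zygosity"] == "MZ"]
    pairs = mz["pair_id"].unique()
    if len(pairs) == 0:
        raise ValueError("cohort contains no MZ pairs")
    rng = np.random.default_rng(seed)
    flip = pd.Series(rng.integers(0, 2, size=len(pairs)) * 2 - 1, index=pairs)

    t1 = mz[mz["twin"] == 1].set_index("pair_id")[CLPM_COLUMNS]
    t2 = mz[mz["twin"] == 2].set_index("pair_id")[CLPM_COLUMNS]
    common = t1.index.intersection(t2.index)
    diff = (t1.loc[common] - t2.loc[common]).mul(flip.loc[common], axis=0)
    return diff.reset_index()


def diff_descriptives(diff: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in CLPM_COLUMNS:
        v = diff[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        rows.append({"measure": col, "n": int(ok.sum()),
                     "mean": float(np.nanmean(v)), "sd": float(np.nanstd(v, ddof=1))})
    return pd.DataFrame(rows)


def diff_correlations(diff: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations across all difference columns.

    Constant columns yield undefined (NaN) entries; at least 3 pairs are
    required.
    """
    if len(diff) < 3:
        raise ValueError("need at least 3 MZ pairs for correlations")
    sub = diff[CLPM_COLUMNS]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = sub.corr(min_periods=3)
    return corr


def fit_diff_clpm(diff: pd.DataFrame, n_boot: int = 0, seed: int = 0) -> CLPMFit:
    """CLPM on MZ difference scores; optional bootstrap CIs when n_boot > 0."""
    fit = fit_clpm(diff)
    if n_boot:
        fit = bootstrap_clpm(diff, n_boot=n_boot, seed=seed, fit=fit)
    return fit
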