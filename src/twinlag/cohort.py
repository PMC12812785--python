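"""Synthetic twin-cohort generation under a component-level cross-lagged ACE process.

Two traits are tracked across three measurement occasions (ages 9, 12, 16):
``P`` — a general psychopathology (p-factor) score — and ``H`` — the child-rated
home environment. Each trait pair evolves as the sum of three latent processes,
one per variance component:

* ``A`` additive genetic: correlated 1.0 across MZ co-twins, 0.5 across DZ;
* ``C`` shared environment: correlated 1.0 in both zygosities;
* ``E`` nonshared environment: uncorrelated across co-twins.

Each component X follows a lag-1 vector autoregression over occasions,
``x_{t+1} = B_X x_t + zeta_{X,t+1}``, with its own wave-1 covariance,
transition matrices and innovation covariances. The observed phenotype is the
sum of the three components plus optional linear age and sex effects. Because
the generating component processes are known exactly, every downstream
estimator (CLPM, biometric cross-lagged ACE, MZ differences) can be checked
against ground truth.

Trait order is [P, H] everywhere; transition matrices are row = outcome trait,
column = predictor trait.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRAITS = ("P", "H")
WAVES = (9, 12, 16)
COMPONENTS = ("A", "C", "E")

#: cross-twin correlation of each component's latent scores, by zygosity
CROSS_TWIN_R = {
    "MZ": {"A": 1.0, "C": 1.0, "E": 0.0},
    "DZ": {"A": 0.5, "C": 1.0, "E": 0.0},
}

#: canonical cohort CSV column order (items appended after these)
COHORT_COLUMNS = [
    "pair_id", "zygosity", "twin", "sex",
    "age_9", "age_12", "age_16",
    "p_parent_9", "p_parent_12", "p_parent_16",
    "p_twin_9", "p_twin_12", "p_twin_16",
    "chaos_9", "chaos_12", "chaos_16",
    "disc_9", "disc_12", "disc_16",
]

MEASURE_COLUMNS = COHORT_COLUMNS[7:]


def _as_matrix(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got shape {m.shape}")
    return m


def _check_psd(m: np.ndarray, name: str, tol: float = 1e-10) -> None:
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    lo = float(np.linalg.eigvalsh(m).min())
    if lo < -tol:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {lo:.3e})")


@dataclass
class ComponentProcess:
    """Latent lag-1 process of one variance component over three occasions."""

    component: str
    sigma1: np.ndarray
    B12: np.ndarray
    B23: np.ndarray
    psi2: np.ndarray
    psi3: np.ndarray

    def __post_init__(self):
        if self.component not in COMPONENTS:
            raise ValueError(f"component must be one of {COMPONENTS}, got {self.component!r}")
        for name in ("sigma1", "B12", "B23", "psi2", "psi3"):
            setattr(self, name, _as_matrix(getattr(self, name), f"{self.component}.{name}"))
        for name in ("sigma1", "psi2", "psi3"):
            _check_psd(getattr(self, name), f"{self.component}.{name}")

    def wave_covs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Component covariance at each occasion, Sigma_{X,t}."""
        s1 = self.sigma1
        s2 = self.B12 @ s1 @ self.B12.T + self.psi2
        s3 = self.B23 @ s2 @ self.B23.T + self.psi3
        return s1, s2, s3

    def within_block(self) -> np.ndarray:
        """6x6 within-person covariance of (P9,H9,P12,H12,P16,H16) for this component."""
        s1, s2, s3 = self.wave_covs()
        c21 = self.B12 @ s1
        c31 = self.B23 @ c21
        c32 = self.B23 @ s2
        out = np.zeros((6, 6))
        out[0:2, 0:2] = s1
        out[2:4, 2:4] = s2
        out[4:6, 4:6] = s3
        out[2:4, 0:2] = c21
        out[4:6, 0:2] = c31
        out[4:6, 2:4] = c32
        out[0:2, 2:4] = c21.T
        out[0:2, 4:6] = c31.T
        out[2:4, 4:6] = c32.T
        return out


@dataclass
class GenSpec:
    """Full generating model for a synthetic twin cohort.

    ``age_effect`` and ``sex_effect`` are per-trait slopes injected into the
    observed scores (per year of age centred at the wave mean, and for
    female = 1 vs male = 0). ``chaos_disc_r`` controls the correlation between
    the two home-environment indicators whose mean reproduces the latent H.
    """

    processes: dict[str, ComponentProcess]
    n_pairs: int = 6212
    prop_mz: float = 0.344
    prop_female: float = 0.509
    age_means: tuple[float, float, float] = (9.02, 11.31, 16.32)
    age_sds: tuple[float, float, float] = (0.29, 0.72, 0.68)
    age_effect: tuple[float, float] = (0.0, 0.0)
    sex_effect: tuple[float, float] = (0.0, 0.0)
    item_loadings: dict[int, tuple[float, ...]] | None = None
    missing_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    attrition_w3: float = 0.0
    chaos_disc_r: float = 0.3
    rater: str = "twin"
    seed: int = 0

    def __post_init__(self):
        if set(self.processes) != set(COMPONENTS):
            raise ValueError(f"processes must contain exactly {COMPONENTS}")
        for x, proc in self.processes.items():
            if proc.component != x:
                raise ValueError(f"process keyed {x!r} is labelled {proc.component!r}")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        for name in ("prop_mz", "prop_female", "attrition_w3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for r in self.missing_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rates must be in [0, 1], got {r}")
        if self.rater not in ("parent", "twin"):
            raise ValueError("rater must be 'parent' or 'twin'")
        if not -1.0 < self.chaos_disc_r <= 1.0:
            raise ValueError("chaos_disc_r must be in (-1, 1]")
        if self.item_loadings:
            for wave, lams in self.item_loadings.items():
                for lam in lams:
                    if not 0.0 < lam <= 1.0:
                        raise ValueError(
                            f"item loading {lam} at wave {wave} outside (0, 1]")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs, "prop_mz": self.prop_mz,
            "prop_female": self.prop_female,
            "age_means": list(self.age_means), "age_sds": list(self.age_sds),
            "age_effect": list(self.age_effect), "sex_effect": list(self.sex_effect),
            "missing_rates": list(self.missing_rates),
            "attrition_w3": self.attrition_w3, "chaos_disc_r": self.chaos_disc_r,
            "rater": self.rater, "seed": self.seed,
        }
        if self.item_loadings:
            d["item_loadings"] = {int(w): list(map(float, l))
                                  for w, l in self.item_loadings.items()}
        for x, proc in self.processes.items():
            for name in ("sigma1", "B12", "B23", "psi2", "psi3"):
                d[f"{x}.{name}"] = [float(v) for v in getattr(proc, name).ravel()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenSpec":
        d = dict(d)
        procs = {}
        for x in COMPONENTS:
            kw = {name: np.array(d.pop(f"{x}.{name}"), dtype=float).reshape(2, 2)
                  for name in ("sigma1", "B12", "B23", "psi2", "psi3")}
            procs[x] = ComponentProcess(component=x, **kw)
        if "item_loadings" in d and d["item_loadings"] is not None:
            d["item_loadings"] = {int(w): tuple(l) for w, l in d["item_loadings"].items()}
        for key in ("age_means", "age_sds", "age_effect", "sex_effect", "missing_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(processes=procs, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GenSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def p_column(self, wave: int) -> str:
        return f"p_{self.rater}_{wave}"


# ---------------------------------------------------------------------------
# expected covariance structure
# ---------------------------------------------------------------------------

def build_expected_cov(spec: GenSpec, zygosity: str) -> np.ndarray:
    """Model-implied 12x12 covariance of (twin1: P9,H9,...,H16; twin2: same).

    The cross-twin block of component X equals r_X times its within-twin
    block, because the co-twins' latent processes share the same transition
    matrices and every wave-1 / innovation covariance is scaled by r_X.
    """
    if zygosity not in CROSS_TWIN_R:
        raise ValueError(f"unknown zygosity code {zygosity!r}; expected MZ or DZ")
    within = np.zeros((6, 6))
    cross = np.zeros((6, 6))
    for x in COMPONENTS:
        w = spec.processes[x].within_block()
        within += w
        cross += CROSS_TWIN_R[zygosity][x] * w
    return np.block([[within, cross], [cross, within]])


def phenotypic_wave_covs(spec: GenSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total phenotypic 2x2 covariance at each wave (sum over components)."""
    covs = [proc.wave_covs() for proc in (spec.processes[x] for x in COMPONENTS)]
    return tuple(sum(c[t] for c in covs) for t in range(3))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _streams(seed: int):
    """Fixed-order child RNG streams: demographics, latent, items, missingness."""
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(s) for s in children)


def simulate_cohort(spec: GenSpec) -> pd.DataFrame:
    """Draw a twin cohort from the generating model; deterministic given the seed.

    Pairs are i.i.d. zero-mean Gaussian with the zygosity-appropriate expected
    covariance. The home trait H is emitted as two indicators (``chaos``,
    ``disc``) constructed as H +/- a twin-specific split noise so that they
    correlate at ``chaos_disc_r`` while their mean equals H exactly.
    """
    rng_demo, rng_latent, _, _ = _streams(spec.seed)
    n = spec.n_pairs

    is_mz = rng_demo.random(n) < spec.prop_mz
    zyg = np.where(is_mz, "MZ", "DZ")
    # MZ co-twins share sex; DZ co-twins drawn independently
    sex_pair = rng_demo.random(n) < spec.prop_female
    sex2_dz = rng_demo.random(n) < spec.prop_female
    sex1 = sex_pair
    sex2 = np.where(is_mz, sex_pair, sex2_dz)
    ages = np.column_stack([
        rng_demo.normal(m, s, size=n) for m, s in zip(spec.age_means, spec.age_sds)
    ])  # shared within pair

    latent = np.empty((n, 12))
    for code in ("MZ", "DZ"):
        rows = zyg == code
        if not rows.any():
            continue
        cov = build_expected_cov(spec, code)
        # eigen factor (not Cholesky) so PSD-boundary specs — e.g. MZ pairs
        # with no E variance — reproduce exact within-pair duplication
        vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
        vals = np.where(vals > vals.max() * 1e-12, vals, 0.0)
        L = vecs * np.sqrt(vals)
        latent[rows] = rng_latent.standard_normal((int(rows.sum()), 12)) @ L.T

    # split noise turning H into two indicators correlating at chaos_disc_r
    r_cd = spec.chaos_disc_r
    h_var = np.array([phenotypic_wave_covs(spec)[t][1, 1] for t in range(3)])
    split_var = h_var * (1.0 - r_cd) / (1.0 + r_cd)
    delta = rng_latent.standard_normal((n, 2, 3)) * np.sqrt(split_var)

    records = []
    a_eff = np.asarray(spec.age_effect)
    s_eff = np.asarray(spec.sex_effect)
    for twin_idx, sex in ((1, sex1), (2, sex2)):
        row = {"pair_id": np.arange(1, n + 1), "zygosity": zyg,
               "twin": np.full(n, twin_idx),
               "sex": np.where(sex, "F", "M")}
        offset = 0 if twin_idx == 1 else 6
        for t, wave in enumerate(WAVES):
            row[f"age_{wave}"] = ages[:, t]
            age_c = ages[:, t] - spec.age_means[t]
            p = latent[:, offset + 2 * t] + a_eff[0] * age_c + s_eff[0] * sex
            h = latent[:, offset + 2 * t + 1] + a_eff[1] * age_c + s_eff[1] * sex
            d = delta[:, twin_idx - 1, t]
            row[spec.p_column(wave)] = p
            row[f"chaos_{wave}"] = h + d
            row[f"disc_{wave}"] = h - d
        records.append(pd.DataFrame(row))

    cohort = pd.concat(records, ignore_index=True)
    cohort = cohort.sort_values(["pair_id", "twin"], ignore_index=True)
    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            cohort[col] = np.nan
    return cohort[COHORT_COLUMNS]


def simulate_items(cohort: pd.DataFrame, spec: GenSpec) -> pd.DataFrame:
    """Append continuous indicator columns per wave for the spec's rater.

    Each item k at a wave is ``loading_k * z(p) + sqrt(1 - loading_k^2) * noise``
    so items have unit variance in expectation and item-factor correlation
    equal to the loading. Returns the cohort unchanged when no loadings are set.
    """
    if not spec.item_loadings:
        return cohort
    _, _, rng_items, _ = _streams(spec.seed)
    out = cohort.copy()
    for wave, lams in sorted(spec.item_loadings.items()):
        col = spec.p_column(wave)
        vals = out[col].to_numpy(dtype=float)
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        z = (vals - mu) / sd
        for k, lam in enumerate(lams, start=1):
            noise = rng_items.standard_normal(len(out))
            out[f"item_{spec.rater}_{wave}_{k}"] = lam * z + np.sqrt(1.0 - lam**2) * noise
    return out


def inject_missingness(cohort: pd.DataFrame, spec: GenSpec) -> pd.DataFrame:
    """Blank measure cells at per-wave MCAR rates; apply wave-3 pair attrition."""
    out = cohort.copy()
    *_, rng_miss = _streams(spec.seed)

    def wave_measure_cols(wave):
        suffix = f"_{wave}"
        cols = [c for c in out.columns
                if c.endswith(suffix) and not c.startswith("age")]
        cols += [c for c in out.columns if c.startswith("item_")
                 and c.split("_")[2] == str(wave)]
        return cols

    for t, wave in enumerate(WAVES):
        rate = spec.missing_rates[t]
        if rate <= 0:
            continue
        cols = wave_measure_cols(wave)
        mask = rng_miss.random((len(out), len(cols))) < rate
        vals = out[cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        out[cols] = vals
    if spec.attrition_w3 > 0:
        pair_ids = out["pair_id"].unique()
        dropped = pair_ids[rng_miss.random(len(pair_ids)) < spec.attrition_w3]
        out.loc[out["pair_id"].isin(dropped), wave_measure_cols(WAVES[2])] = np.nan
    return out


# ---------------------------------------------------------------------------
# path decomposition and share targeting
# ---------------------------------------------------------------------------

_TRANSITIONS = {"12": 0, "23": 1}


def path_contributions(processes: dict[str, ComponentProcess], transition: str):
    """Per-component additive contributions to the phenotypic lag-1 path matrix.

    For transition t -> t+1 the phenotypic path matrix is
    ``B_ph = (sum_X B_X Sigma_{X,t}) Sigma_t^{-1}`` and component X contributes
    ``B_X Sigma_{X,t} Sigma_t^{-1}`` to it. Returns (contrib, M) where both are
    dicts over components: contrib[X] is the 2x2 contribution matrix and
    M[X] = Sigma_{X,t} Sigma_t^{-1} (the sensitivity of contributions to B_X).
    """
    if transition not in _TRANSITIONS:
        raise ValueError(f"transition must be one of {list(_TRANSITIONS)}")
    t = _TRANSITIONS[transition]
    wave_covs = {x: processes[x].wave_covs() for x in COMPONENTS}
    sigma_t = sum(wave_covs[x][t] for x in COMPONENTS)
    if abs(np.linalg.det(sigma_t)) < 1e-14:
        raise ValueError(f"total phenotypic covariance at transition {transition} is singular")
    inv = np.linalg.inv(sigma_t)
    M = {x: wave_covs[x][t] @ inv for x in COMPONENTS}
    B_attr = "B12" if transition == "12" else "B23"
    contrib = {x: getattr(processes[x], B_attr) @ M[x] for x in COMPONENTS}
    return contrib, M


def solve_shares(base: GenSpec, path: tuple[str, str, str],
                 target_shares: tuple[float, float, float]) -> GenSpec:
    """Rescale one path's component coefficients to hit target A/C/E shares.

    ``path`` is (from_trait, to_trait, transition) with traits in {"P", "H"}
    and transition in {"12", "23"}. The phenotypic path magnitude is held
    fixed; each component's lagged coefficient B_X[to, from] is shifted so its
    additive contribution equals target_share * phenotypic path.
    """
    frm, to, transition = path
    if frm not in TRAITS or to not in TRAITS:
        raise ValueError(f"traits must be in {TRAITS}")
    shares = np.asarray(target_shares, dtype=float)
    if (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-8:
        raise ValueError("target shares must be nonnegative and sum to 1")
    j, k = TRAITS.index(frm), TRAITS.index(to)

    spec = copy.deepcopy(base)
    contrib, M = path_contributions(spec.processes, transition)
    total = sum(contrib[x][k, j] for x in COMPONENTS)
    B_attr = "B12" if transition == "12" else "B23"
    for share, x in zip(shares, COMPONENTS):
        want = share * total
        have = contrib[x][k, j]
        mjj = M[x][j, j]
        if abs(mjj) < 1e-12:
            if abs(want - have) > 1e-10:
                raise ValueError(
                    f"infeasible target: component {x} has no variance on "
                    f"predictor trait {frm} at transition {transition}")
            continue
        getattr(spec.processes[x], B_attr)[k, j] += (want - have) / mjj

    new_contrib, _ = path_contributions(spec.processes, transition)
    new_total = sum(new_contrib[x][k, j] for x in COMPONENTS)
    achieved = np.array([new_contrib[x][k, j] for x in COMPONENTS])
    if abs(new_total) > 1e-12 and np.max(np.abs(achieved / new_total - shares)) > 1e-8:
        raise RuntimeError("share targeting failed to converge")  # pragma: no cover
    return spec


# ---------------------------------------------------------------------------
# spec builders used throughout the test/acceptance surface
# ---------------------------------------------------------------------------

def flat_ace_spec(p_ace: tuple[float, float, float],
                  h_ace: tuple[float, float, float] = (0.2, 0.3, 0.5),
                  trait_r: float = 0.3, **kwargs) -> GenSpec:
    """Stationary no-transmission spec: every wave repeats the wave-1 ACE split.

    All transitions are zero and innovations equal the wave-1 component
    covariances, so each occasion is an independent draw with the requested
    variance fractions; traits correlate at ``trait_r`` within each component.
    """
    procs = {}
    zero = np.zeros((2, 2))
    for x, (vp, vh) in zip(COMPONENTS, zip(p_ace, h_ace)):
        s = np.array([[vp, trait_r * np.sqrt(vp * vh)],
                      [trait_r * np.sqrt(vp * vh), vh]])
        procs[x] = ComponentProcess(x, s, zero.copy(), zero.copy(), s.copy(), s.copy())
    return GenSpec(processes=procs, **kwargs)


def crosslag_spec(p_ace: tuple[float, float, float],
                  h_ace: tuple[float, float, float],
                  B12: np.ndarray, B23: np.ndarray,
                  trait_r: float = 0.0, **kwargs) -> GenSpec:
    """Spec in which all three components share the phenotypic transitions.

    Component wave covariances are held stationary (psi = sigma1 - B sigma1 B'),
    so wave-1 variance fractions persist and path shares initially equal the
    variance fractions of the predictor trait; use solve_shares afterwards to
    move individual paths to target decompositions.
    """
    B12 = np.asarray(B12, dtype=float)
    B23 = np.asarray(B23, dtype=float)
    procs = {}
    for x, (vp, vh) in zip(COMPONENTS, zip(p_ace, h_ace)):
        s = np.array([[vp, trait_r * np.sqrt(vp * vh)],
                      [trait_r * np.sqrt(vp * vh), vh]])
        psi2 = s - B12 @ s @ B12.T
        psi3 = s - B23 @ s @ B23.T
        for name, m in (("psi2", psi2), ("psi3", psi3)):
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(
                    f"transitions too large for stationary innovations ({x}.{name})")
        procs[x] = ComponentProcess(x, s, B12.copy(), B23.copy(), psi2, psi3)
    return GenSpec(processes=procs, **kwargs)


def study_spec(rater: str = "twin", **kwargs) -> GenSpec:
    """Default cohort emulating the study conditions for the given rater.

    Wave-1 variance fractions and phenotypic stabilities/cross-lags are set to
    the reported estimates for that rater's model; stability-path and
    cross-lag decompositions are steered to the reported dominant shares via
    solve_shares. Demographics, attrition and measurement structure use the
    study defaults on GenSpec.
    """
    if rater == "parent":
        p_ace, h_ace = (0.51, 0.15, 0.34), (0.19, 0.51, 0.30)
        B12 = np.array([[0.60, 0.04], [0.18, 0.40]])
        B23 = np.array([[0.60, 0.08], [0.10, 0.40]])
    elif rater == "twin":
        p_ace, h_ace = (0.47, 0.13, 0.40), (0.19, 0.51, 0.30)
        B12 = np.array([[0.40, 0.11], [0.14, 0.40]])
        B23 = np.array([[0.40, 0.02], [0.13, 0.40]])
    else:
        raise ValueError("rater must be 'parent' or 'twin'")
    kwargs.setdefault("rater", rater)
    kwargs.setdefault("missing_rates", (0.1, 0.1, 0.1))
    kwargs.setdefault("attrition_w3", 0.5)
    spec = crosslag_spec(p_ace, h_ace, B12, B23, trait_r=0.3, **kwargs)
    for path, shares in STUDY_DECOMP_TARGETS[rater].items():
        spec = solve_shares(spec, path, shares)
    return spec


#: reported univariate variance profiles (a2, c2, e2) per rater/trait/age.
#: a2 values are the published heritabilities; the C components of the
#: profiles are not all printed and are fixed once here: parent p uses the
#: conventional small shared-environment values (0.08 at 12), twin p carries
#: its reported ~40% nonshared share, and the home environment is
#: C-dominant in line with its stability decomposition.
STUDY_UNIVARIATE_PROFILES = {
    "parent_p_9": (0.51, 0.15, 0.34),
    "parent_p_12": (0.67, 0.08, 0.25),
    "parent_p_16": (0.59, 0.12, 0.29),
    "twin_p_9": (0.47, 0.13, 0.40),
    "twin_p_12": (0.42, 0.15, 0.43),
    "twin_p_16": (0.46, 0.14, 0.40),
    "home_env_9": (0.19, 0.51, 0.30),
    "home_env_12": (0.19, 0.51, 0.30),
    "home_env_16": (0.31, 0.40, 0.29),
}

#: reported standardized cross-lags per rater model (CLPM generating values);
#: autoregressions 0.70 (p) / 0.40 (home), wave-1 r = .30, innovation r = .20
STUDY_CLPM_PARAMS = {
    "parent": dict(auto=(0.70, 0.40), r1=0.30, innov_r=0.20,
                   cross={"P->H": 0.18, "H->P": 0.04},
                   cross2={"P->H": 0.10, "H->P": 0.08}),
    "twin": dict(auto=(0.70, 0.40), r1=0.30, innov_r=0.20,
                 cross={"P->H": 0.14, "H->P": 0.11},
                 cross2={"P->H": 0.13, "H->P": 0.02}),
}

#: decomposition share targets steered into the study specs (see study_spec);
#: only the dominant printed share per path is externally reported.
STUDY_DECOMP_TARGETS = {
    "parent": {("P", "P", "12"): (0.68, 0.16, 0.16),
               ("P", "P", "23"): (0.75, 0.125, 0.125),
               ("H", "H", "12"): (0.15, 0.65, 0.20),
               ("H", "H", "23"): (0.17, 0.63, 0.20)},
    "twin": {("P", "P", "12"): (0.77, 0.115, 0.115),
             ("P", "P", "23"): (0.76, 0.12, 0.12),
             ("H", "H", "12"): (0.13, 0.74, 0.13),
             ("H", "H", "23"): (0.135, 0.73, 0.135),
             ("P", "H", "23"): (0.54, 0.32, 0.14)},
}


def mzdiff_recovery_spec(e_cross: float = 0.09, e_auto: float = 0.2,
                         n_pairs: int = 5000, seed: int = 0) -> GenSpec:
    """All-MZ spec whose standardized E-process p9->home12 cross-lag is set.

    A and C carry stability only; E is stationary with equal trait variances,
    so the raw E cross coefficient equals the standardized E path that the
    MZ-differences CLPM estimates.
    """
    def stationary(component, s, B):
        return ComponentProcess(component, s, B, np.diag(np.diag(B)),
                                s - B @ s @ B.T,
                                s - np.diag(np.diag(B)) @ s @ np.diag(np.diag(B)).T)

    BE = np.array([[e_auto, 0.0], [e_cross, e_auto]])
    procs = {
        "A": stationary("A", 0.4 * np.eye(2), 0.5 * np.eye(2)),
        "C": stationary("C", 0.3 * np.eye(2), 0.4 * np.eye(2)),
        "E": stationary("E", 0.3 * np.eye(2), BE),
    }
    return GenSpec(processes=procs, n_pairs=n_pairs, prop_mz=1.0, seed=seed)


# ---------------------------------------------------------------------------
# cohort CSV I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cols = COHORT_COLUMNS + [c for c in cohort.columns if c not in COHORT_COLUMNS]
    cohort[cols].to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zygosity": str, "sex": str})
    missing = [c for c in COHORT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    bad = set(df["zygosity"].dropna().unique()) - {"MZ", "DZ"}
    if bad:
        raise ValueError(f"invalid zygosity codes in cohort CSV: {sorted(bad)}")
    counts = df.groupby("pair_id").size()
    if (counts != 2).any():
        raise ValueError("each pair_id must appear exactly twice in the cohort")
    return df
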