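"""Generator correctness: implied covariances, simulation moments, share targeting."""

import numpy as np
import pandas as pd
import pytest

import twinlag as tl
from twinlag.cohort import COMPONENTS, ComponentProcess

from conftest import random_process


def brute_force_cov(spec, zygosity):
    """Independent oracle: enumerate the linear map from all innovations to all
    observations and form M Cov(innov) M'.

    The stacked innovation vector holds, per component, twin1's wave-1 scores
    and wave-2/3 innovations followed by twin2's (12 entries per component).
    """
    r = {"MZ": {"A": 1.0, "C": 1.0, "E": 0.0},
         "DZ": {"A": 0.5, "C": 1.0, "E": 0.0}}[zygosity]
    total = np.zeros((12, 12))
    for x in COMPONENTS:
        p = spec.processes[x]
        # map from one twin's 6 innovations to their 6 observations
        m = np.zeros((6, 6))
        m[0:2, 0:2] = np.eye(2)
        m[2:4, 0:2] = p.B12
        m[2:4, 2:4] = np.eye(2)
        m[4:6, 0:2] = p.B23 @ p.B12
        m[4:6, 2:4] = p.B23
        m[4:6, 4:6] = np.eye(2)
        M = np.block([[m, np.zeros((6, 6))], [np.zeros((6, 6)), m]])
        blk = np.zeros((6, 6))
        for i, mat in enumerate((p.sigma1, p.psi2, p.psi3)):
            blk[2 * i:2 * i + 2, 2 * i:2 * i + 2] = mat
        innov_cov = np.block([[blk, r[x] * blk], [r[x] * blk, blk]])
        total += M @ innov_cov @ M.T
    return total


class TestExpectedCov:
    def test_matches_brute_force_oracle(self, random_spec):
        for zyg in ("MZ", "DZ"):
            got = tl.build_expected_cov(random_spec, zyg)
            want = brute_force_cov(random_spec, zyg)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_e_only_has_zero_cross_twin_block(self):
        zero = np.zeros((2, 2))
        null = ComponentProcess("A", zero, zero, zero, zero, zero)
        procs = {"A": null,
                 "C": ComponentProcess("C", zero, zero, zero, zero, zero),
                 "E": ComponentProcess("E", np.eye(2), 0.3 * np.eye(2),
                                       0.3 * np.eye(2), np.eye(2), np.eye(2))}
        spec = tl.GenSpec(processes=procs, n_pairs=10)
        for zyg in ("MZ", "DZ"):
            cov = tl.build_expected_cov(spec, zyg)
            np.testing.assert_allclose(cov[:6, 6:], 0.0, atol=1e-12)

    def test_a_only_mz_cross_equals_within_and_dz_is_half(self):
        zero = np.zeros((2, 2))
        procs = {"A": ComponentProcess("A", np.eye(2), zero, zero, zero, zero),
                 "C": ComponentProcess("C", zero, zero, zero, zero, zero),
                 "E": ComponentProcess("E", zero, zero, zero, zero, zero)}
        spec = tl.GenSpec(processes=procs, n_pairs=10)
        mz = tl.build_expected_cov(spec, "MZ")
        dz = tl.build_expected_cov(spec, "DZ")
        np.testing.assert_allclose(mz[:6, 6:], mz[:6, :6], atol=1e-12)
        np.testing.assert_allclose(dz[:2, 6:8], 0.5 * np.eye(2), atol=1e-12)

    def test_symmetric_psd_and_zygosity_invariant_within(self, random_spec):
        mz = tl.build_expected_cov(random_spec, "MZ")
        dz = tl.build_expected_cov(random_spec, "DZ")
        for cov in (mz, dz):
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.linalg.eigvalsh(cov).min() >= -1e-10
        np.testing.assert_allclose(mz[:6, :6], dz[:6, :6], atol=1e-12)
        np.testing.assert_allclose(mz[:6, :6], mz[6:, 6:], atol=1e-12)

    def test_unknown_zygosity_and_bad_matrix_raise(self, random_spec):
        with pytest.raises(ValueError, match="zygosity"):
            tl.build_expected_cov(random_spec, "XX")
        with pytest.raises(ValueError, match="sigma1"):
            ComponentProcess("A", -np.eye(2), np.zeros((2, 2)), np.zeros((2, 2)),
                             np.eye(2), np.eye(2))


class TestSimulation:
    def test_deterministic_given_seed(self):
        spec = tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=50, seed=7)
        a = tl.simulate_cohort(spec)
        b = tl.simulate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_empirical_moments_match_implied(self):
        rng = np.random.default_rng(3)
        procs = {x: random_process(rng, x) for x in COMPONENTS}
        spec = tl.GenSpec(processes=procs, n_pairs=50_000, prop_mz=1.0, seed=13)
        cohort = tl.simulate_cohort(spec)
        # reconstruct the latent 12-vector from p and the chaos/disc mean
        cols = []
        for twin in (1, 2):
            sub = cohort[cohort["twin"] == twin].sort_values("pair_id")
            for w in (9, 12, 16):
                cols.append(sub[f"p_twin_{w}"].to_numpy())
                cols.append(0.5 * (sub[f"chaos_{w}"] + sub[f"disc_{w}"]).to_numpy())
        Y = np.column_stack(cols)
        emp = np.cov(Y.T)
        want = tl.build_expected_cov(spec, "MZ")
        # elementwise Monte-Carlo 3-SE bound for covariance entries
        n = spec.n_pairs
        se = np.sqrt((np.outer(np.diag(want), np.diag(want)) + want**2) / n)
        assert (np.abs(emp - want) < 3.5 * se + 1e-8).all()

    def test_prop_mz_one_yields_no_dz(self):
        spec = tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=40, prop_mz=1.0, seed=5)
        assert set(tl.simulate_cohort(spec)["zygosity"]) == {"MZ"}

    def test_invalid_n_pairs_rejected(self):
        with pytest.raises(ValueError, match="n_pairs"):
            tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=0)

    def test_chaos_disc_correlation_near_target(self):
        spec = tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=20_000, seed=2,
                                chaos_disc_r=0.3)
        cohort = tl.simulate_cohort(spec)
        r = np.corrcoef(cohort["chaos_9"], cohort["disc_9"])[0, 1]
        assert abs(r - 0.3) < 0.02


class TestItems:
    def test_loading_one_reproduces_factor(self):
        spec = tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=300, seed=4,
                                item_loadings={9: (1.0,)})
        cohort = tl.simulate_items(tl.simulate_cohort(spec), spec)
        p = cohort["p_twin_9"]
        z = (p - p.mean()) / p.std(ddof=0)
        np.testing.assert_allclose(cohort["item_twin_9_1"], z, atol=1e-10)

    def test_item_factor_correlations_match_loadings(self):
        lams = (0.7, 0.6, 0.5)
        spec = tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=25_000, seed=6,
                                item_loadings={9: lams})
        cohort = tl.simulate_items(tl.simulate_cohort(spec), spec)
        n = 2 * spec.n_pairs
        for k, lam in enumerate(lams, start=1):
            r = np.corrcoef(cohort["p_twin_9"], cohort[f"item_twin_9_{k}"])[0, 1]
            assert abs(r - lam) < 3.0 / np.sqrt(n) + 0.01

    def test_no_loadings_returns_unchanged(self, small_cohort):
        cohort, spec = small_cohort
        assert tl.simulate_items(cohort, spec) is cohort

    def test_bad_loading_rejected(self):
        with pytest.raises(ValueError, match="loading"):
            tl.flat_ace_spec((0.5, 0.2, 0.3), item_loadings={9: (1.2,)})


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, small_cohort):
        cohort, spec = small_cohort
        pd.testing.assert_frame_equal(tl.inject_missingness(cohort, spec), cohort)

    def test_attrition_rate_recovered(self):
        spec = tl.flat_ace_spec((0.5, 0.2, 0.3), n_pairs=10_000, seed=8,
                                attrition_w3=0.5)
        cohort = tl.inject_missingness(tl.simulate_cohort(spec), spec)
        observed = cohort.groupby("pair_id")["p_twin_16"].apply(
            lambda s: s.notna().any()).mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(observed - 0.5) < 3 * se

    def test_rate_one_blanks_whole_wave(self, small_cohort):
        cohort, spec = small_cohort
        spec2 = tl.GenSpec(processes=spec.processes, n_pairs=spec.n_pairs,
                           missing_rates=(0.0, 1.0, 0.0), seed=spec.seed)
        out = tl.inject_missingness(cohort, spec2)
        assert out["p_twin_12"].isna().all() and out["chaos_12"].isna().all()
        assert out["age_12"].notna().all()


class TestSolveShares:
    def base(self):
        B = np.array([[0.5, 0.1], [0.12, 0.4]])
        return tl.crosslag_spec((0.4, 0.3, 0.3), (0.2, 0.4, 0.4), B, B)

    def shares_of(self, spec, path):
        contrib, _ = tl.path_contributions(spec.processes, path[2])
        j, k = ("P", "H").index(path[0]), ("P", "H").index(path[1])
        raw = np.array([contrib[x][k, j] for x in COMPONENTS])
        return raw / raw.sum()

    def test_pure_a_target_zeroes_other_coefficients(self):
        spec = tl.solve_shares(self.base(), ("P", "H", "12"), (1.0, 0.0, 0.0))
        assert spec.processes["C"].B12[1, 0] == pytest.approx(0.0, abs=1e-10)
        assert spec.processes["E"].B12[1, 0] == pytest.approx(0.0, abs=1e-10)

    def test_equal_target_gives_equal_contributions(self):
        spec = tl.solve_shares(self.base(), ("H", "P", "23"),
                               (1 / 3, 1 / 3, 1 / 3))
        np.testing.assert_allclose(self.shares_of(spec, ("H", "P", "23")),
                                   1 / 3, atol=1e-9)

    def test_reported_cross_lag_split_reproduced(self):
        # dominant-genetic cross-lag split seen for p at 12 -> home env at 16
        spec = tl.solve_shares(self.base(), ("P", "H", "23"), (0.54, 0.32, 0.14))
        np.testing.assert_allclose(self.shares_of(spec, ("P", "H", "23")),
                                   (0.54, 0.32, 0.14), atol=1e-9)

    def test_phenotypic_path_held_fixed(self):
        base = self.base()
        contrib, _ = tl.path_contributions(base.processes, "12")
        before = sum(contrib[x][1, 0] for x in COMPONENTS)
        spec = tl.solve_shares(base, ("P", "H", "12"), (0.7, 0.2, 0.1))
        contrib2, _ = tl.path_contributions(spec.processes, "12")
        after = sum(contrib2[x][1, 0] for x in COMPONENTS)
        assert after == pytest.approx(before, abs=1e-10)

    def test_infeasible_target_raises(self):
        # A has no variance on the predictor trait H, so an all-A H->P path
        # cannot be manufactured
        B_a = np.diag([0.5, 0.0])
        B_ce = np.array([[0.5, 0.1], [0.0, 0.4]])
        procs = {}
        for x, s, B in zip(COMPONENTS,
                           (np.diag([0.4, 0.0]), np.diag([0.3, 0.5]),
                            np.diag([0.3, 0.5])),
                           (B_a, B_ce, B_ce)):
            procs[x] = ComponentProcess(x, s, B, B, s - B @ s @ B.T,
                                        s - B @ s @ B.T)
        spec = tl.GenSpec(processes=procs, n_pairs=10)
        with pytest.raises(ValueError, match="infeasible"):
            tl.solve_shares(spec, ("H", "P", "12"), (1.0, 0.0, 0.0))

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError, match="shares"):
            tl.solve_shares(self.base(), ("P", "H", "12"), (0.5, 0.4, 0.4))


class TestIO:
    def test_yaml_roundtrip(self, random_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        random_spec.to_yaml(path)
        back = tl.GenSpec.from_yaml(path)
        for x in COMPONENTS:
            for name in ("sigma1", "B12", "B23", "psi2", "psi3"):
                np.testing.assert_allclose(getattr(back.processes[x], name),
                                           getattr(random_spec.processes[x], name))
        assert back.n_pairs == random_spec.n_pairs

    def test_cohort_csv_roundtrip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        path = tmp_path / "cohort.csv"
        tl.write_cohort(cohort, path)
        back = tl.read_cohort(path)
        assert list(back.columns[:4]) == ["pair_id", "zygosity", "twin", "sex"]
        assert len(back) == len(cohort)
        np.testing.assert_allclose(back["p_twin_9"], cohort["p_twin_9"],
                                   rtol=1e-4)

    def test_read_rejects_bad_zygosity(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        bad = cohort.copy()
        bad.loc[0, "zygosity"] = "XX"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="zygosity"):
            tl.read_cohort(path)
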