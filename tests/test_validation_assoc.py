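import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolrfi import synthetic_data as sd
from poolrfi import validation_assoc as va
from poolrfi.io_formats import PedigreeRecord, PedigreeTable
from poolrfi.reference_data import load_genotype_effects_reference

from conftest import random_pedigree


def build_cohort(seed, n, **kwargs):
    cfg = sd.SimConfig(seed=seed, n_validation=n, **kwargs)
    gt, pheno, ped, truth = sd.simulate_validation_cohort(cfg)
    A, ids = va.build_a_matrix(ped)
    idx = {a: i for i, a in enumerate(ids)}
    y = pheno["rfi"].to_numpy()
    X = np.column_stack([np.ones(len(y)), (pheno["sex"] == "M").astype(float)])
    Z = np.zeros((len(y), len(ids)))
    for r, b in enumerate(pheno["bird_id"]):
        Z[r, idx[b]] = 1.0
    return gt, pheno, ped, truth, A, ids, y, X, Z


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = PedigreeTable(
            [PedigreeRecord("a", None, None, "M"), PedigreeRecord("b", None, None, "F")]
        )
        A, _ = va.build_a_matrix(ped)
        assert np.allclose(A, np.eye(2))

    def test_parent_offspring_half(self, trio_pedigree):
        A, ids = va.build_a_matrix(trio_pedigree)
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["S1"], i["O1"]] == pytest.approx(0.5)
        assert A[i["O1"], i["O1"]] == pytest.approx(1.0)

    def test_full_sibs_and_inbred_offspring(self, fullsib_pedigree):
        A, ids = va.build_a_matrix(fullsib_pedigree)
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["A"], i["B"]] == pytest.approx(0.5)
        assert A[i["C"], i["C"]] == pytest.approx(1.25)  # F = 0.25

    def test_symmetry_and_eigenvalues(self, rng):
        ped = random_pedigree(rng, n_founders=8, n_offspring=40)
        A, _ = va.build_a_matrix(ped)
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() >= -1e-10
        assert (np.diag(A) >= 1.0 - 1e-12).all()
        assert (np.diag(A) <= 2.0 + 1e-12).all()

    def test_gene_dropping_oracle(self, rng):
        # independent Monte-Carlo oracle: expected IBD sharing from allele
        # dropping; A_ij = 2 * kinship(i, j)
        ped = random_pedigree(rng, n_founders=6, n_offspring=14)
        A, ids = va.build_a_matrix(ped)
        by_id = {r.animal_id: r for r in ped.records}
        order = ped.topological_order()
        n_drops = 40_000
        alleles = {}
        counter = 0
        for animal in order:
            rec = by_id[animal]
            if rec.sire_id is None:
                a1 = np.full(n_drops, counter)
                a2 = np.full(n_drops, counter + 1)
                counter += 2
            else:
                sire = alleles[rec.sire_id]
                dam = alleles[rec.dam_id]
                pick_s = rng.integers(0, 2, n_drops)
                pick_d = rng.integers(0, 2, n_drops)
                a1 = np.where(pick_s == 0, sire[0], sire[1])
                a2 = np.where(pick_d == 0, dam[0], dam[1])
            alleles[animal] = (a1, a2)
        for i in range(0, len(ids), 4):
            for j in range(i, len(ids), 4):
                xi, xj = alleles[ids[i]], alleles[ids[j]]
                if i == j:
                    kin = 0.5 * (1.0 + (xi[0] == xi[1]).mean())
                else:
                    kin = 0.25 * sum(
                        (xi[a] == xj[b]).mean() for a in range(2) for b in range(2)
                    )
                assert 2 * kin == pytest.approx(A[i, j], abs=0.02)

    def test_cycle_error(self):
        with pytest.raises(Exception, match="cycle"):
            PedigreeTable(
                [
                    PedigreeRecord("a", "b", None, "M"),
                    PedigreeRecord("b", None, "a", "F"),
                ]
            )


class TestSolveBlup:
    def test_infinite_shrinkage_limit(self):
        _, pheno, _, _, A, ids, y, X, Z = build_cohort(21, 100, snp_effects={})
        spec = va.MixedModelSpec(
            y=y, X=X, Z=Z, A=A, sigma2_a=1.0, sigma2_e=1e9, animal_ids=ids
        )
        sol = va.solve_blup(spec)
        assert np.abs(sol.ebv).max() < 1e-3
        males = y[X[:, 1] == 1].mean()
        females = y[X[:, 1] == 0].mean()
        assert sol.b_hat[0] == pytest.approx(females, abs=1e-3)
        assert sol.b_hat[0] + sol.b_hat[1] == pytest.approx(males, abs=1e-3)

    def test_matches_dense_solver_oracle(self, rng):
        for seed in range(5):
            _, pheno, _, _, A, ids, y, X, Z = build_cohort(
                30 + seed, 40, val_n_sires=4, val_n_dams=8, snp_effects={}
            )
            spec = va.MixedModelSpec(
                y=y, X=X, Z=Z, A=A, sigma2_a=300.0, sigma2_e=700.0, animal_ids=ids
            )
            sol = va.solve_blup(spec)
            lam = 700.0 / 300.0
            M = np.block(
                [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.linalg.inv(A)]]
            )
            expected = np.linalg.solve(M, np.concatenate([X.T @ y, Z.T @ y]))
            assert np.allclose(sol.b_hat, expected[:2], rtol=1e-8)
            assert np.allclose(sol.ebv, expected[2:], rtol=1e-8, atol=1e-10)
            assert sol.relative_residual <= 1e-8

    def test_ebv_correlates_with_true_bv(self):
        _, pheno, _, truth, A, ids, y, X, Z = build_cohort(
            42, 800, sigma2_a=300.0, sigma2_e=700.0, snp_effects={}
        )
        spec = va.MixedModelSpec(
            y=y, X=X, Z=Z, A=A, sigma2_a=300.0, sigma2_e=700.0, animal_ids=ids
        )
        sol = va.solve_blup(spec)
        ebv = sol.ebv_series().loc[pheno["bird_id"]].to_numpy()
        true_bv = np.array([truth.true_breeding_values[b] for b in pheno["bird_id"]])
        assert np.corrcoef(ebv, true_bv)[0, 1] >= 0.5


class TestRemlEstimation:
    def test_matches_dense_em_oracle(self):
        _, _, _, _, A, ids, y, X, Z = build_cohort(
            50, 60, val_n_sires=5, val_n_dams=10, snp_effects={}
        )
        n, p, q = len(y), 2, A.shape[0]
        Ainv = np.linalg.inv(A)
        sa = se = 0.5 * np.var(y, ddof=1)
        for _ in range(25):
            lam = se / sa
            M = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ainv]])
            C = np.linalg.inv(M)
            solv = C @ np.concatenate([X.T @ y, Z.T @ y])
            b, a = solv[:p], solv[p:]
            Caa = C[p:, p:]
            sa = (a @ Ainv @ a + se * np.trace(Ainv @ Caa)) / q
            se = (y @ y - b @ (X.T @ y) - a @ (Z.T @ y)) / (n - p)
        res = va.estimate_variance_components(y, X, Z, A, tol=0.0, max_iterations=25)
        assert res.sigma2_a == pytest.approx(sa, rel=1e-8)
        assert res.sigma2_e == pytest.approx(se, rel=1e-8)

    def test_zero_variance_error(self):
        _, _, _, _, A, ids, y, X, Z = build_cohort(51, 30, snp_effects={})
        with pytest.raises(ValueError, match="zero variance"):
            va.estimate_variance_components(np.ones_like(y), X, Z, A)

    def test_h2_recovery_single_cohort(self):
        _, _, _, _, A, ids, y, X, Z = build_cohort(
            52, 400, sigma2_a=300.0, sigma2_e=700.0, snp_effects={}
        )
        res = va.estimate_variance_components(y, X, Z, A, tol=1e-8, max_iterations=5000)
        assert res.converged
        assert abs(res.heritability - 0.3) < 0.2


class TestWaldTest:
    def test_exact_linear_clamps_p(self):
        dosage = np.array([0.0, 1.0, 2.0] * 10)
        ebv = 3.0 * dosage + 1.0
        beta, se, p = va.wald_snp_test(ebv, dosage)
        assert beta == pytest.approx(3.0)
        assert p == 1e-300

    def test_monomorphic_flagged(self):
        beta, se, p = va.wald_snp_test(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        assert p == 1.0 and np.isnan(beta)

    def test_missing_dropped_pairwise(self):
        dosage = np.array([0.0, 1.0, 2.0, np.nan, 0.0, 2.0])
        ebv = np.arange(6, dtype=float)
        beta, se, p = va.wald_snp_test(ebv, dosage)
        assert np.isfinite(beta) and 0 < p <= 1

    def test_matches_slope_t_statistic_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            dosage = rng.integers(0, 3, size=n).astype(float)
            if len(np.unique(dosage)) < 2:
                continue
            ebv = rng.normal(size=n) + 0.3 * dosage
            beta, se, p = va.wald_snp_test(ebv, dosage)
            lr = stats.linregress(dosage, ebv)
            assert beta == pytest.approx(lr.slope, rel=1e-10)
            assert se == pytest.approx(lr.stderr, rel=1e-10)
            t2 = (lr.slope / lr.stderr) ** 2
            assert p == pytest.approx(stats.chi2.sf(t2, 1), rel=1e-10)


class TestGenotypeLsm:
    @staticmethod
    def _oracle_lsm(y, geno, sex):
        # independent normal-equation oracle with explicit dummy design
        g_levels = sorted(set(geno))
        s_levels = sorted(set(sex))
        X = np.ones((len(y), 1))
        for lvl in s_levels[1:]:
            X = np.hstack([X, (np.asarray(sex) == lvl).astype(float)[:, None]])
        for lvl in g_levels[1:]:
            X = np.hstack([X, (np.asarray(geno) == lvl).astype(float)[:, None]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        out = {}
        for gi, lvl in enumerate(g_levels):
            c = np.zeros(X.shape[1])
            c[0] = 1.0
            for j in range(1, len(s_levels)):
                c[j] = 1.0 / len(s_levels)
            if gi > 0:
                c[len(s_levels) - 1 + gi] = 1.0
            out[lvl] = float(c @ beta)
        return out

    def test_sex_balanced_equals_raw_means(self, rng):
        geno = np.repeat(["AA", "AG", "GG"], 20)
        sex = np.tile(["M", "F"], 30)
        y = rng.normal(size=60) + 5.0 * (geno == "AA")
        table, _ = va.genotype_lsm(y, geno, sex)
        for _, row in table.iterrows():
            assert row["lsm"] == pytest.approx(y[geno == row["genotype"]].mean(), abs=1e-9)

    def test_planted_additive_recovery(self):
        cfg = sd.SimConfig(
            seed=60, n_validation=600, sigma2_a=0.0, sigma2_e=0.01,
            sex_effect=5.0, snp_effects={0: (10.0, 0.0)},
        )
        gt, pheno, _, _ = sd.simulate_validation_cohort(cfg)
        g = gt.dosage.iloc[:, 0].to_numpy()
        labels = np.array(["AA", "AG", "GG"], dtype=object)[g.astype(int)]
        table, overall_p = va.genotype_lsm(
            pheno["rfi"].to_numpy(), labels, pheno["sex"].to_numpy()
        )
        lsm = dict(zip(table["genotype"], table["lsm"]))
        assert lsm["AG"] - lsm["AA"] == pytest.approx(10.0, abs=0.1)
        assert lsm["GG"] - lsm["AG"] == pytest.approx(10.0, abs=0.1)
        assert overall_p < 1e-10
        a_eff, d_eff = va.effects_from_lsm(lsm)
        assert a_eff == pytest.approx(-10.0, abs=0.1)
        assert d_eff == pytest.approx(0.0, abs=0.1)

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(50):
            n = 60
            geno = rng.choice(["AA", "AG", "GG"], size=n)
            sex = rng.choice(["M", "F"], size=n)
            if len(set(geno)) < 2 or len(set(sex)) < 2:
                continue
            y = rng.normal(size=n)
            table, _ = va.genotype_lsm(y, geno, sex)
            oracle = self._oracle_lsm(y, geno, sex)
            for _, row in table.iterrows():
                assert row["lsm"] == pytest.approx(oracle[row["genotype"]], abs=1e-8)

    def test_letter_groups_separate_extremes(self, rng):
        # AA and AG indistinguishable, GG far away
        y = np.concatenate([np.zeros(60), np.full(30, 50.0)])
        geno = np.repeat(["AA", "AG", "GG"], 30)
        sex = np.tile(["M", "F"], 45)
        y = y + rng.normal(0, 1.0, size=90)
        table, _ = va.genotype_lsm(y, geno, sex)
        letters = dict(zip(table["genotype"], table["letters_05"]))
        assert letters["GG"] != letters["AA"]
        assert set(letters["AA"]) & set(letters["AG"])


class TestAdditiveDominance:
    def test_reference_rows_reproduced(self):
        ref = load_genotype_effects_reference()
        for snp, sub in ref.groupby("snp"):
            lsm = dict(zip(sub["genotype"], sub["lsm"]))
            a_eff, d_eff = va.effects_from_lsm(lsm)
            assert a_eff == pytest.approx(sub["additive_effect"].iloc[0], abs=0.01), snp
            assert d_eff == pytest.approx(sub["dominance_effect"].iloc[0], abs=0.01), snp

    def test_midpoint_heterozygote_zero_dominance(self, rng):
        for _ in range(20):
            x, z = rng.normal(size=2) * 10
            a_eff, d_eff = va.additive_dominance(x, (x + z) / 2, z)
            assert d_eff == pytest.approx(0.0, abs=1e-12)
            assert a_eff == pytest.approx((x - z) / 2, abs=1e-12)

    def test_alphabetical_hom_ordering(self):
        a_eff, d_eff = va.effects_from_lsm({"TT": 1.0, "CC": 5.0, "TC": 2.0})
        assert a_eff == pytest.approx((5.0 - 1.0) / 2)

    def test_bad_class_structure(self):
        with pytest.raises(ValueError):
            va.effects_from_lsm({"AA": 1.0, "GG": 2.0})
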