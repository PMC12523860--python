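"""Permutation importance, significance selection, null-calibration
mechanics (the full-scale null study lives in the acceptance suite)."""

import numpy as np
import pytest

from pleionet import gwas
from pleionet.datatypes import SnpMap


def snp_map(p):
    return SnpMap(
        np.array([f"s{j}" for j in range(p)], dtype=object),
        np.ones(p, int),
        np.arange(1, p + 1) * 1000,
    )


@pytest.fixture()
def fitted(rng):
    """A single-active-SNP model with clear signal."""
    n, p = 200, 10
    x = rng.standard_normal((n, p))
    w = np.zeros((p, 2))
    w[3] = [1.0, -0.8]
    y = x @ w + 0.2 * rng.standard_normal((n, 2))
    sol = gwas.mt_enet_fit(x[:150], y[:150], 0.05, 1.0)
    return sol, x[150:], y[150:]


class TestPermutationImportance:
    def test_zero_rows_get_exact_zero(self, fitted, rng):
        sol, xv, yv = fitted
        scores = gwas.permutation_importance(sol, xv, yv, seed=1)
        inactive = np.setdiff1d(np.arange(10), sol.active_rows())
        assert np.all(scores.ris[inactive] == 0.0)

    def test_single_predictor_explains_all(self, fitted):
        sol, xv, yv = fitted
        assert list(sol.active_rows()) == [3]
        scores = gwas.permutation_importance(sol, xv, yv, n_perm_per_snp=50, seed=2)
        # the only predictor carries ~100% of predictive variance
        assert scores.ris[3, 0] > 60.0
        assert scores.ris[3, 1] > 60.0

    def test_constant_column_permutation_is_identity(self, rng):
        # permuting a constant validation column cannot change predictions,
        # so its delta-R2 (and RIS) is exactly 0 even though the row is active
        n, p = 120, 3
        x = rng.standard_normal((n, p))
        x[:, 2] = 1.0
        w = np.array([[1.0, 0.5], [0.0, 0.0], [0.3, 0.3]])
        y = x @ w + 0.1 * rng.standard_normal((n, 2))
        sol = gwas.EnetSolution(w, np.zeros(2), 0.01, 1.0, 1, True, 0.0)
        scores = gwas.permutation_importance(sol, x, y, n_perm_per_snp=5, seed=1)
        assert scores.ris[2, 0] == 0.0 and scores.ris[2, 1] == 0.0
        assert scores.ris[0, 0] > 0.0

    def test_abort_on_zero_baseline(self, rng):
        n, p = 50, 4
        x = rng.standard_normal((n, p))
        w = np.zeros((p, 2))
        w[0] = [1.0, 1.0]
        sol = gwas.EnetSolution(w, np.zeros(2), 0.1, 1.0, 1, True, 0.0)
        y_const = np.ones((n, 2))  # no variance -> baseline R^2 is 0
        with pytest.raises(RuntimeError, match="R\\^2"):
            gwas.permutation_importance(sol, x, y_const, seed=0)

    def test_absolute_mode_smaller_than_relative_when_r2_below_one(self, fitted):
        sol, xv, yv = fitted
        rel = gwas.permutation_importance(sol, xv, yv, seed=3, mode="relative")
        ab = gwas.permutation_importance(sol, xv, yv, seed=3, mode="absolute")
        assert ab.ris[3, 0] <= rel.ris[3, 0] + 1e-9


class TestSelectSignificant:
    def test_threshold_is_strict(self):
        scores = gwas.ImportanceScores(
            np.array([[1.0, 0.0], [1.0001, 2.0], [0.5, 1.0]]), np.array([0.5, 0.5]), 0
        )
        table = gwas.select_significant(scores, snp_map(3))
        assert list(table["significant_adg"]) == [False, True, False]
        assert list(table["significant_wbsf"]) == [False, True, False]

    def test_all_zero_selects_nothing(self):
        scores = gwas.ImportanceScores(np.zeros((4, 2)), np.array([0.5, 0.5]), 0)
        table = gwas.select_significant(scores, snp_map(4))
        assert not table["significant_adg"].any()
        assert not table["significant_wbsf"].any()

    def test_matches_brute_force(self, rng):
        ris = rng.uniform(0, 3, size=(20, 2))
        scores = gwas.ImportanceScores(ris, np.array([0.5, 0.5]), 0)
        table = gwas.select_significant(scores, snp_map(20))
        np.testing.assert_array_equal(table["significant_adg"].to_numpy(), ris[:, 0] > 1.0)
        np.testing.assert_array_equal(table["significant_wbsf"].to_numpy(), ris[:, 1] > 1.0)


class TestNullCalibration:
    def test_single_replicate_summary(self, rng):
        n, p = 80, 12
        x = rng.standard_normal((n, p))
        y = rng.standard_normal((n, 2))
        import pandas as pd

        plan = gwas.SplitPlan(np.arange(60), np.arange(60, 80), 2016)
        out = gwas.null_calibration(x, y, plan, lam=0.05, alpha=0.8, n_null=1, seed=4)
        assert out["p95"] == out["max_ris"][0]

    def test_deterministic_for_seed(self, rng):
        n, p = 80, 12
        x = rng.standard_normal((n, p))
        y = rng.standard_normal((n, 2))
        plan = gwas.SplitPlan(np.arange(60), np.arange(60, 80), 2016)
        a = gwas.null_calibration(x, y, plan, 0.05, 0.8, n_null=5, seed=5)
        b = gwas.null_calibration(x, y, plan, 0.05, 0.8, n_null=5, seed=5)
        np.testing.assert_array_equal(a["max_ris"], b["max_ris"])

    def test_fully_shrunk_replicates_contribute_zero(self, rng):
        n, p = 80, 12
        x = rng.standard_normal((n, p))
        y = rng.standard_normal((n, 2))
        plan = gwas.SplitPlan(np.arange(60), np.arange(60, 80), 2016)
        out = gwas.null_calibration(x, y, plan, lam=1e6, alpha=1.0, n_null=3, seed=6)
        assert np.all(out["max_ris"] == 0.0)


class TestPlantedQtlRecovery:
    def test_top_scores_localize_to_planted_loci(self):
        """With every QTL pleiotropic and strong genetic signal, the
        top-importance SNPs for both traits fall inside the planted
        loci's LD neighbourhoods."""
        from pleionet import simulate
        from pleionet.datatypes import SimulationConfig

        cfg = SimulationConfig(
            n_animals=500, n_snps=1000, n_chromosomes=5, n_qtl=40,
            shared_fraction=1.0, target_h2=(0.6, 0.5), target_rg=0.6,
            qtl_effect_corr=0.6, missing_trait2_fraction=0.0, seed=55,
        )
        geno = simulate.simulate_genotypes(cfg)
        qtl = simulate.assign_qtl_effects(geno.snp_map, cfg)
        pheno, truth = simulate.simulate_phenotypes(geno, qtl, cfg)
        x, y, _ = gwas.standardize(geno.dosage_float(), truth.genetic_values)
        lam = gwas.lambda_max(x[:400], y[:400]) / 20
        sol = gwas.mt_enet_fit(x[:400], y[:400], lam, 0.9)
        scores = gwas.permutation_importance(sol, x[400:], y[400:], seed=56)
        qtl_pos = {
            (int(c), int(p))
            for c, p, m in zip(
                geno.snp_map.chromosome, geno.snp_map.position, qtl.pleiotropy_mask
            )
            if m != 0
        }
        for t in range(2):
            top = np.argsort(scores.ris[:, t])[::-1][:10]
            near = 0
            for j in top:
                cj, pj = int(geno.snp_map.chromosome[j]), int(geno.snp_map.position[j])
                if any(c == cj and abs(p - pj) <= 100_000 for c, p in qtl_pos):
                    near += 1
            assert near >= 8, f"trait {t}: only {near}/10 top SNPs near planted QTLs"


class TestPredictiveAbilityMonotoneInH2:
    def test_validation_accuracy_increases_with_heritability(self):
        from pleionet import simulate, qc as qcmod
        from pleionet.datatypes import SimulationConfig

        accs = []
        for h2 in (0.05, 0.3, 0.6):
            cfg = SimulationConfig(
                n_animals=500, n_snps=600, n_chromosomes=3, n_qtl=120,
                target_h2=(h2, h2), target_rg=0.0, qtl_effect_corr=0.0,
                missing_trait2_fraction=0.0, seed=57,
            )
            geno = simulate.simulate_genotypes(cfg)
            qtl = simulate.assign_qtl_effects(geno.snp_map, cfg)
            pheno, _ = simulate.simulate_phenotypes(geno, qtl, cfg)
            pheno, _r = qcmod.build_contemporary_groups(pheno)
            y_adj = gwas.adjust_for_cg(pheno)
            x, y, _ = gwas.standardize(geno.dosage_float(), y_adj)
            split = gwas.forward_split(pheno, 2016)
            lam = gwas.lambda_max(x[split.train_idx], y[split.train_idx]) / 10
            sol = gwas.mt_enet_fit(x[split.train_idx], y[split.train_idx], lam, 0.9)
            acc, _ = gwas._score(x[split.validation_idx] @ sol.W, y[split.validation_idx])
            accs.append(acc)
        assert accs[0] < accs[1] < accs[2]
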