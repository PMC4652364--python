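"""Score-test mechanics, inflation factor, SNP effects and PVE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salmopred import gwas, relmat, simdata, varcomp
from salmopred.relmat import RelationshipMatrix
from salmopred.varcomp import AnimalModelSpec

from conftest import make_genotypes


def fixed_vc(s2a, s2e):
    return varcomp.VarianceComponents(
        sigma2_a=s2a, sigma2_e=s2e, se_a=0.0, se_e=0.0, cov_ae=0.0,
        loglik=0.0, converged=True, boundary=False, n_iter=1)


@pytest.fixture(scope="module")
def fitted_small(small_pop_module):
    pop = small_pop_module
    G = relmat.g_matrix_vanraden(pop.genotypes)
    model = varcomp.make_model(pop.phenotypes, G, "weight")
    vc = varcomp.reml_fit(model)
    return pop, model, vc


@pytest.fixture(scope="module")
def small_pop_module(request):
    return request.getfixturevalue("small_pop")


class TestBonferroni:
    def test_reference_panel_threshold(self):
        assert gwas.bonferroni(0.05, 111_908) == pytest.approx(4.468e-7, rel=1e-3)

    def test_per_chromosome_uses_chromosome_count(self, fitted_small):
        pop, model, vc = fitted_small
        res = gwas.grammar_scan(model, vc, pop.genotypes.subset(samples=model.ids))
        counts = res.table["chrom"].value_counts()
        for chrom, thr in res.chrom_thresholds.items():
            assert thr == pytest.approx(0.05 / counts[chrom])
        assert res.genomewide_threshold == pytest.approx(0.05 / res.n_tests)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            gwas.bonferroni(0.05, 0)


class TestGrammarScan:
    def test_orthogonal_dosage_scores_zero(self):
        rng = np.random.default_rng(0)
        n = 20
        K = np.eye(n) + 0.2
        ids = [f"i{j}" for j in range(n)]
        model = AnimalModelSpec(
            y=rng.standard_normal(n), X=np.ones((n, 1)), ids=ids,
            K=RelationshipMatrix(kind="G", ids=ids, values=K))
        vc = fixed_vc(1.0, 1.0)
        V = vc.sigma2_a * K + vc.sigma2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        X = model.X
        P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        Py = P @ model.y
        # build a centered dosage vector exactly orthogonal to Py
        g = rng.standard_normal(n)
        g -= g.mean()
        g -= (g @ Py) / (Py @ Py) * Py  # Py sums to zero, so g stays centered
        gm = make_genotypes(g[:, None], sample_ids=ids)
        res = gwas.grammar_scan(model, vc, gm)
        assert res.table["stat"].iloc[0] == pytest.approx(0.0, abs=1e-16)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_phenotype_shift(self, fitted_small):
        pop, model, vc = fitted_small
        panel = pop.genotypes.subset(samples=model.ids)
        sub = panel.subset(snp_ids=panel.snps["id"].tolist()[:100])
        res1 = gwas.grammar_scan(model, vc, sub)
        shifted = AnimalModelSpec(y=model.y + 1000.0, X=model.X,
                                  ids=model.ids, K=model.K)
        res2 = gwas.grammar_scan(shifted, vc, sub)
        np.testing.assert_allclose(res1.table["stat"], res2.table["stat"],
                                   atol=1e-8)

    def test_monomorphic_snp_skipped(self, fitted_small):
        pop, model, vc = fitted_small
        dos = np.column_stack([np.zeros(len(model.ids)),
                               np.tile([0.0, 1, 2, 1], len(model.ids))[:len(model.ids)]])
        gm = make_genotypes(dos, sample_ids=model.ids)
        res = gwas.grammar_scan(model, vc, gm)
        assert ("M0", "monomorphic") in res.skipped
        assert res.n_tests == 1

    def test_single_qtl_power(self):
        # a QTL explaining 20% of the additive variance should be the top
        # association at or immediately next to itself in nearly every run
        hits = 0
        for seed in range(20):
            cfg = simdata.SimConfig(
                n_sires=10, n_dams=20, n_families=20, total_offspring=300,
                n_snps=900, n_causal=60, n_chromosomes=9, qtl_pve=0.20,
                n_base_generations=4, n_base_individuals=30)
            pop = simdata.simulate_population(cfg, seed=100 + seed)
            G = relmat.g_matrix_vanraden(pop.genotypes)
            model = varcomp.make_model(pop.phenotypes, G, "weight")
            vc = varcomp.reml_fit(model)
            res = gwas.grammar_scan(model, vc,
                                    pop.genotypes.subset(samples=model.ids))
            qtl = pop.causal_effects["snp"].iloc[0]
            order = pop.genotypes.snps["id"].tolist()
            top = res.table.sort_values("stat", ascending=False)["snp"].iloc[0]
            if abs(order.index(top) - order.index(qtl)) <= 1:
                hits += 1
        assert hits >= 18


class TestGenomicInflation:
    def test_uniform_null_near_one(self):
        p = (np.arange(1, 10001) - 0.5) / 10000
        assert gwas.genomic_inflation(p) == pytest.approx(1.0, abs=0.01)

    def test_enrichment_inflates(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=5000) ** 2
        assert gwas.genomic_inflation(p) > 1.1

    def test_hand_median(self):
        chis = np.array([0.1, 0.3, 0.4549, 1.0, 2.0])
        p = stats.chi2.sf(chis, df=1)
        assert gwas.genomic_inflation(p) == pytest.approx(1.0, abs=1e-3)


class TestSnpEffects:
    def noiseless_model(self, dosage, class_means, n_per_class=4):
        g = np.repeat(dosage, n_per_class).astype(float)
        y = np.repeat(class_means, n_per_class).astype(float)
        n = len(y)
        ids = [f"i{j}" for j in range(n)]
        model = AnimalModelSpec(
            y=y, X=np.ones((n, 1)), ids=ids,
            K=RelationshipMatrix(kind="G", ids=ids, values=np.eye(n)))
        return model, g

    def test_alpha_delta_from_class_means(self):
        model, g = self.noiseless_model([0, 1, 2], [10.0, 8.0, 2.0])
        rec = gwas.snp_effect_fit(model, fixed_vc(0.0, 1.0), g)
        assert rec.alpha == pytest.approx(4.0)
        assert rec.delta == pytest.approx(2.0)  # 8 - (10 + 2)/2
        assert rec.n_classes == 3

    def test_midway_heterozygote_zero_dominance(self):
        model, g = self.noiseless_model([0, 1, 2], [10.0, 6.0, 2.0])
        rec = gwas.snp_effect_fit(model, fixed_vc(0.0, 1.0), g)
        assert rec.delta == pytest.approx(0.0, abs=1e-10)

    def test_additive_alpha_equals_dosage_slope(self):
        model, g = self.noiseless_model([0, 1, 2], [10.0, 7.0, 4.0])
        rec = gwas.snp_effect_fit(model, fixed_vc(0.0, 1.0), g)
        slope = np.polyfit(g, model.y, 1)[0]
        assert rec.alpha == pytest.approx(-slope, abs=1e-6)

    def test_two_classes_omit_dominance(self):
        model, g = self.noiseless_model([0, 1], [10.0, 8.0], n_per_class=5)
        rec = gwas.snp_effect_fit(model, fixed_vc(0.0, 1.0), g)
        assert rec.delta is None and rec.n_classes == 2

    def test_single_class_rejected(self):
        model, g = self.noiseless_model([1, 1], [5.0, 5.0])
        with pytest.raises(ValueError, match="single"):
            gwas.snp_effect_fit(model, fixed_vc(0.0, 1.0), g)

    def test_simulated_qtl_effect_recovered(self):
        cfg = simdata.SimConfig(
            n_sires=10, n_dams=20, n_families=20, total_offspring=400,
            n_snps=400, n_causal=40, n_chromosomes=4, qtl_pve=0.30,
            n_base_generations=0)
        pop = simdata.simulate_population(cfg, seed=21)
        G = relmat.g_matrix_vanraden(pop.genotypes)
        model = varcomp.make_model(pop.phenotypes, G, "weight")
        vc = varcomp.reml_fit(model)
        qtl = pop.causal_effects.iloc[0]
        sub = pop.genotypes.subset(samples=model.ids)
        j = sub.snps.index[sub.snps["id"] == qtl["snp"]][0]
        rec = gwas.snp_effect_fit(model, vc, sub.dosages[:, j], marker=qtl["snp"])
        # alpha estimates the per-allele substitution effect of the QTL
        assert abs(abs(rec.alpha) - abs(qtl["weight"])) <= 3 * rec.se_alpha


class TestPve:
    def test_reference_worked_numerator(self):
        # p=0.57, q=0.43, alpha=4.42, delta=1.27 -> 2pq(a+d(q-p))^2 = 8.82
        v_a = 132.2
        out = gwas.pve(0.57, 0.43, 4.42, 1.27, v_a)
        assert out * v_a == pytest.approx(8.82, abs=0.005)
        assert out == pytest.approx(0.067, abs=0.001)

    def test_null_effects_zero(self):
        assert gwas.pve(0.5, 0.5, 0.0, 0.0, 10.0) == 0.0

    def test_monomorphic_zero(self):
        assert gwas.pve(1.0, 0.0, 3.0, 1.0, 10.0) == 0.0

    def test_two_class_reduction_exact(self):
        full = gwas.pve(0.7, 0.3, 2.0, None, 5.0, n_classes=2)
        assert full == pytest.approx(2 * 0.7 * 0.3 * 4.0 / 5.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gwas.pve(0.5, 0.5, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            gwas.pve(0.5, 0.6, 1.0, 0.0, 1.0)
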