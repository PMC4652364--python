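"""Mendelian QC, LD pruning, density reduction and random subsetting."""

import numpy as np
import pandas as pd
import pytest

from salmopred import genio, qc

from conftest import make_genotypes


def trio(sire_dos, dam_dos, kid_dos):
    gm = make_genotypes(np.array([sire_dos, dam_dos, kid_dos], dtype=float),
                        sample_ids=["S", "D", "K"])
    ped = genio.Pedigree.from_records(pd.DataFrame({
        "id": ["S", "D", "K"], "sire": ["0", "0", "S"], "dam": ["0", "0", "D"]}))
    return gm, ped


class TestMendelianErrors:
    def test_impossible_transmission_counted(self):
        gm, ped = trio([0], [0], [2])
        per_snp, per_ind = qc.mendelian_error_rate(gm, ped)
        assert per_snp.iloc[0] == 1.0
        assert per_ind["K"] == 1.0

    def test_obligate_het_consistent(self):
        gm, ped = trio([0], [2], [1])
        per_snp, per_ind = qc.mendelian_error_rate(gm, ped)
        assert per_snp.iloc[0] == 0.0

    def test_obligate_het_violated(self):
        gm, ped = trio([0], [2], [0])
        per_snp, _ = qc.mendelian_error_rate(gm, ped)
        assert per_snp.iloc[0] == 1.0

    def test_missing_parent_uses_duo_rule(self):
        # sire 0 transmits 0; offspring 2 impossible whatever the dam carries
        gm, ped = trio([0], [np.nan], [2])
        per_snp, _ = qc.mendelian_error_rate(gm, ped)
        assert per_snp.iloc[0] == 1.0

    def test_simulated_panel_error_free(self, small_pop):
        per_snp, per_ind = qc.mendelian_error_rate(small_pop.genotypes,
                                                   small_pop.pedigree)
        assert np.nanmax(per_snp.to_numpy()) == 0.0
        assert per_ind.max() == 0.0

    def test_no_trio_flagged(self):
        gm = make_genotypes([[0.0], [1.0]])
        ped = genio.Pedigree.from_records(pd.DataFrame({
            "id": ["IND0", "IND1"], "sire": ["0", "0"], "dam": ["0", "0"]}))
        with pytest.warns(UserWarning, match="no resolvable"):
            per_snp, per_ind = qc.mendelian_error_rate(gm, ped)
        assert per_snp.isna().all()


class TestFilterPanel:
    def test_maf_threshold_is_strict(self):
        # 50 unrelated samples: 5 hets -> MAF 0.05 kept, 4 hets -> 0.04 removed
        dos = np.zeros((50, 2))
        dos[:5, 0] = 1.0
        dos[:4, 1] = 1.0
        gm = make_genotypes(dos)
        ped = genio.Pedigree.from_records(pd.DataFrame({
            "id": gm.samples, "sire": "0", "dam": "0"}))
        with pytest.warns(UserWarning, match="no resolvable"):
            out, report = qc.filter_panel(gm, ped, maf_min=0.05)
        assert out.snps["id"].tolist() == ["M0"]
        assert dict(report.removed)["snp_maf"] == 1

    def test_clean_simulated_data_untouched(self, small_pop):
        out, report = qc.filter_panel(small_pop.genotypes, small_pop.pedigree,
                                      maf_min=0.0)
        assert out.n_snps == small_pop.genotypes.n_snps
        assert out.n_samples == small_pop.genotypes.n_samples
        report.check_totals()

    def test_corrupted_sample_removed_first(self, small_pop):
        gm = small_pop.genotypes
        ped = small_pop.pedigree
        dos = gm.dosages.copy()
        victim = small_pop.offspring_ids[0]
        vi = gm.samples.index(victim)
        pos = {s: i for i, s in enumerate(gm.samples)}
        sire, dam = ped.parents_of(victim)
        si, di = pos[sire], pos[dam]
        # corrupt 10% of the victim's genotypes into obligate errors
        both_hom_ref = (dos[si] == 0) & (dos[di] == 0)
        targets = np.where(both_hom_ref)[0][: max(1, gm.n_snps // 10)]
        dos[vi, targets] = 2.0
        corrupted = genio.GenotypeMatrix(samples=gm.samples, snps=gm.snps,
                                         dosages=dos)
        out, report = qc.filter_panel(corrupted, ped, maf_min=0.0)
        assert victim in report.removed_samples
        assert victim not in out.samples


class TestLdR2:
    def test_duplicate_snp_full_ld(self):
        v = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert qc.ld_r2(v, v) == pytest.approx(1.0)

    def test_uncorrelated_vectors(self):
        a = np.array([0, 0, 2, 2], dtype=float)
        b = np.array([0, 2, 0, 2], dtype=float)
        assert qc.ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # Pearson r = 2 / sqrt(2.75 * 2) on these vectors, so r^2 = 8/11
        a = np.array([0, 0, 1, 2], dtype=float)
        b = np.array([0, 1, 1, 2], dtype=float)
        assert qc.ld_r2(a, b) == pytest.approx(8.0 / 11.0)

    def test_monomorphic_flagged_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = qc.ld_r2(np.zeros(5), np.array([0, 1, 2, 1, 0.0]))
        assert np.isnan(out)


class TestDensityReduction:
    def test_one_snp_per_contig(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(40, 2)).astype(float)
        gm = make_genotypes(dos, contig=["c1", "c1"])
        out, report = qc.density_reduction(gm, maf_min=0.0, miss_max=1.0,
                                           r2_max=1.1)
        assert out.n_snps == 1
        assert dict(report.removed)["snp_contig"] == 1

    def test_ld_prune_strictly_above_threshold(self):
        partner = np.array([0, 0, 1, 2] * 10, dtype=float)
        other = np.array([0, 1, 1, 2] * 10, dtype=float)  # r^2 = 8/11 with partner
        gm = make_genotypes(np.column_stack([partner, other]))
        # r^2 = 8/11 > 0.65: the later SNP of the pair is dropped
        out, _ = qc.density_reduction(gm, r2_max=0.65, maf_min=0.0, miss_max=1.0)
        assert out.snps["id"].tolist() == ["M0"]
        # threshold exactly at r^2: strict inequality keeps both
        out2, _ = qc.density_reduction(gm, r2_max=8.0 / 11.0, maf_min=0.0,
                                       miss_max=1.0)
        assert out2.n_snps == 2

    def test_maf_and_missingness_step(self):
        dos = np.zeros((50, 2))
        dos[:8, 0] = 1.0          # MAF 0.08 < 0.10 -> removed
        dos[:20, 1] = 1.0         # MAF 0.20 kept
        gm = make_genotypes(dos)
        out, _ = qc.density_reduction(gm, maf_min=0.10, miss_max=0.03,
                                      r2_max=1.1)
        assert out.snps["id"].tolist() == ["M1"]

    def test_counts_reconcile_on_simulated_panel(self, small_pop):
        out, report = qc.density_reduction(small_pop.genotypes, maf_min=0.0,
                                           miss_max=1.0)
        report.check_totals()
        assert out.n_snps <= small_pop.genotypes.n_snps


class TestRandomSubsets:
    def test_sizes_and_membership(self, small_pop):
        panels = qc.random_subsets(small_pop.genotypes, sizes=[50, 200], seed=3)
        assert panels[50].n_snps == 50
        all_ids = set(small_pop.genotypes.snps["id"])
        assert set(panels[200].snps["id"]) <= all_ids

    def test_nested(self, small_pop):
        panels = qc.random_subsets(small_pop.genotypes, sizes=[50, 200], seed=3)
        assert set(panels[50].snps["id"]) <= set(panels[200].snps["id"])

    def test_full_size_is_identity(self, small_pop):
        m = small_pop.genotypes.n_snps
        panels = qc.random_subsets(small_pop.genotypes, sizes=[m], seed=0)
        assert panels[m].snps["id"].tolist() == small_pop.genotypes.snps["id"].tolist()

    def test_reproducible(self, small_pop):
        a = qc.random_subsets(small_pop.genotypes, sizes=[100], seed=11)
        b = qc.random_subsets(small_pop.genotypes, sizes=[100], seed=11)
        assert a[100].snps["id"].tolist() == b[100].snps["id"].tolist()

    def test_oversized_request_rejected(self, small_pop):
        with pytest.raises(ValueError, match="exceed"):
            qc.random_subsets(small_pop.genotypes,
                              sizes=[small_pop.genotypes.n_snps + 1], seed=0)
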