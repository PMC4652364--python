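"""Quality control and panel-design reduction on a corrupted dataset.

Injects Mendelian-inconsistent genotypes into one sample, runs the
standard QC (individual and SNP Mendelian filters, then MAF), and then the
density-reduction pipeline (one SNP per contig, LD pruning at r^2 > 0.65,
MAF/missingness).
"""

import numpy as np

from salmopred import genio, qc, simdata

cfg = simdata.SimConfig(n_sires=10, n_dams=20, n_families=20,
                        total_offspring=200, n_snps=2000, n_causal=200,
                        n_chromosomes=10)
pop = simdata.simulate_population(cfg, seed=5)

# corrupt 5% of one offspring's genotypes into obligate Mendelian errors
gm = pop.genotypes
dos = gm.dosages.copy()
victim = pop.offspring_ids[0]
pos = {s: i for i, s in enumerate(gm.samples)}
sire, dam = pop.pedigree.parents_of(victim)
hom_ref = (dos[pos[sire]] == 0) & (dos[pos[dam]] == 0)
targets = np.where(hom_ref)[0][: gm.n_snps // 20]
dos[pos[victim], targets] = 2.0
corrupted = genio.GenotypeMatrix(samples=gm.samples, snps=gm.snps, dosages=dos)

filtered, report = qc.filter_panel(corrupted, pop.pedigree)
print("standard QC (Mendelian > 1%, then MAF < 0.05):")
print(report.summary().to_string(index=False))
print(f"removed samples: {report.removed_samples} (the corrupted fish)")

reduced, red_report = qc.density_reduction(filtered)
print("\ndensity reduction (contig dedup, LD r^2 > 0.65, MAF >= 0.10):")
print(red_report.summary().to_string(index=False))
print(f"panel: {filtered.n_snps} -> {reduced.n_snps} SNPs")

panels = qc.random_subsets(reduced, sizes=[100, 500], seed=5)
print(f"nested random panels: {[p.n_snps for p in panels.values()]} SNPs")
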