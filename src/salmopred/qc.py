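"""SNP and sample quality control, LD-based panel reduction, subsetting.

Two distinct filtering stages are provided:

* :func:`filter_panel` — the primary QC: remove individuals, then SNPs,
  with excessive (>1%) Mendelian-inconsistency rates, then SNPs with minor
  allele frequency below 0.05 (recomputed on the surviving individuals).
* :func:`density_reduction` — the panel-design pipeline for lower marker
  densities: one SNP per genome contig, greedy LD pruning (drop one of each
  pair with r^2 > 0.65), then MAF >= 0.10 and missingness <= 0.03 filters.
  :func:`random_subsets` then draws nested random panels (0.5K, 1K, ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, Pedigree, UNKNOWN_PARENT

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Removal counts per rule, in application order, plus survivors."""

    n_samples_in: int
    n_snps_in: int
    removed: list[tuple[str, int]] = field(default_factory=list)  # (rule, count)
    removed_samples: list[str] = field(default_factory=list)
    removed_snps: dict[str, list[str]] = field(default_factory=dict)
    surviving_samples: list[str] = field(default_factory=list)
    surviving_snps: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["rule", "removed"])

    def check_totals(self) -> None:
        snp_removed = sum(n for rule, n in self.removed if rule.startswith("snp"))
        samp_removed = sum(n for rule, n in self.removed if rule.startswith("sample"))
        assert snp_removed + len(self.surviving_snps) == self.n_snps_in
        assert samp_removed + len(self.surviving_samples) == self.n_samples_in


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

def _mendel_bounds(par: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min/max transmissible dosage contribution from one parent's dosages.

    A parent with dosage 0 transmits allele count 0; dosage 2 transmits 1;
    dosage 1 transmits 0 or 1; an ungenotyped parent (NaN) transmits 0 or 1.
    """
    lo = (par == 2).astype(float)
    hi = 1.0 - (par == 0).astype(float)
    return lo, hi


def mendelian_error_rate(genotypes: GenotypeMatrix, pedigree: Pedigree,
                         ) -> tuple[pd.Series, pd.Series]:
    """Per-SNP and per-offspring Mendelian inconsistency rates.

    A test is informative when the offspring and at least one parent are
    genotyped at the SNP; an error is an offspring dosage outside the range
    transmissible from the (available) parental dosages. Returns
    ``(per_snp_rate, per_individual_rate)``; rates are NaN where no
    informative test exists.
    """
    pos = {s: i for i, s in enumerate(genotypes.samples)}
    trios = []
    for _, row in pedigree.table.iterrows():
        if row["sire"] == UNKNOWN_PARENT and row["dam"] == UNKNOWN_PARENT:
            continue
        if row["id"] not in pos:
            continue
        trios.append((row["id"], pos[row["id"]],
                      pos.get(row["sire"]), pos.get(row["dam"])))
    if not trios:
        warnings.warn("no resolvable parent-offspring trio; Mendelian rates undefined",
                      stacklevel=2)
        empty = pd.Series(np.nan, index=genotypes.snps["id"])
        return empty, pd.Series(dtype=float)

    dos = genotypes.dosages
    m = genotypes.n_snps
    err_snp = np.zeros(m)
    inf_snp = np.zeros(m)
    err_ind = {}
    inf_ind = {}
    for oid, oi, si, di in trios:
        o = dos[oi]
        s = dos[si] if si is not None else np.full(m, np.nan)
        d = dos[di] if di is not None else np.full(m, np.nan)
        s_known = ~np.isnan(s)
        d_known = ~np.isnan(d)
        informative = ~np.isnan(o) & (s_known | d_known)
        lo_s, hi_s = _mendel_bounds(s)
        lo_d, hi_d = _mendel_bounds(d)
        lo_s[~s_known], hi_s[~s_known] = 0.0, 1.0
        lo_d[~d_known], hi_d[~d_known] = 0.0, 1.0
        err = informative & ((o < lo_s + lo_d) | (o > hi_s + hi_d))
        err_snp += err
        inf_snp += informative
        err_ind[oid] = err.sum()
        inf_ind[oid] = informative.sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        snp_rate = np.where(inf_snp > 0, err_snp / np.maximum(inf_snp, 1), np.nan)
    per_snp = pd.Series(snp_rate, index=genotypes.snps["id"])
    per_ind = pd.Series({k: err_ind[k] / inf_ind[k] if inf_ind[k] > 0 else np.nan
                         for k in err_ind})
    return per_snp, per_ind


def filter_panel(genotypes: GenotypeMatrix, pedigree: Pedigree,
                 maf_min: float = 0.05, mendel_max: float = 0.01,
                 ) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the standard QC: Mendelian filters then a MAF filter.

    Individuals with Mendelian error rate strictly above ``mendel_max`` are
    removed first; SNP error rates are then recomputed on the survivors and
    SNPs above the threshold removed; finally SNPs with MAF strictly below
    ``maf_min`` (on surviving individuals) are removed.
    """
    if not (0 <= maf_min <= 1 and 0 <= mendel_max <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    report = QcReport(n_samples_in=genotypes.n_samples, n_snps_in=genotypes.n_snps)

    _, per_ind = mendelian_error_rate(genotypes, pedigree)
    bad_ind = [i for i, r in per_ind.items() if np.isfinite(r) and r > mendel_max]
    report.removed.append(("sample_mendel", len(bad_ind)))
    report.removed_samples = bad_ind
    keep_samples = [s for s in genotypes.samples if s not in set(bad_ind)]
    gm = genotypes.subset(samples=keep_samples)

    per_snp, _ = mendelian_error_rate(gm, pedigree)
    bad_snp = per_snp.index[(per_snp > mendel_max).fillna(False)].tolist()
    report.removed.append(("snp_mendel", len(bad_snp)))
    report.removed_snps["snp_mendel"] = bad_snp
    keep = [s for s in gm.snps["id"] if s not in set(bad_snp)]
    gm = gm.subset(snp_ids=keep)

    maf = gm.maf()
    low = maf < maf_min  # strict: MAF exactly at the threshold is retained
    bad_maf = gm.snps["id"][low].tolist()
    report.removed.append(("snp_maf", len(bad_maf)))
    report.removed_snps["snp_maf"] = bad_maf
    keep = gm.snps["id"][~low].tolist()
    if not keep or not keep_samples:
        raise ValueError("QC removed every SNP or sample")
    gm = gm.subset(snp_ids=keep)

    report.surviving_samples = list(gm.samples)
    report.surviving_snps = gm.snps["id"].tolist()
    report.check_totals()
    for rule, count in report.removed:
        logger.info("qc rule %-12s removed %d", rule, count)
    return gm, report


# ---------------------------------------------------------------------------
# LD and density reduction
# ---------------------------------------------------------------------------

def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    NaN (flagged by a warning) when fewer than two complete pairs remain or
    either SNP is monomorphic among them.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn("LD undefined: monomorphic SNP or <2 complete pairs",
                      stacklevel=2)
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def density_reduction(genotypes: GenotypeMatrix, r2_max: float = 0.65,
                      maf_min: float = 0.10, miss_max: float = 0.03,
                      window: int = 50) -> tuple[GenotypeMatrix, QcReport]:
    """Panel-design reduction: contig dedup, LD pruning, MAF/missingness.

    Steps, in order: (i) keep one SNP per contig (the highest-MAF one);
    (ii) greedy left-to-right LD pruning within each chromosome, dropping
    the later SNP of any pair with r^2 strictly above ``r2_max`` among the
    last ``window`` kept SNPs; (iii) drop SNPs with MAF < ``maf_min`` or
    missingness > ``miss_max``.
    """
    report = QcReport(n_samples_in=genotypes.n_samples, n_snps_in=genotypes.n_snps)
    snps = genotypes.snps.copy()
    snps["_maf"] = genotypes.maf()
    snps["_row"] = np.arange(len(snps))

    # (i) one SNP per contig, keep the highest MAF (ties: first by position)
    order = snps.sort_values(["contig", "_maf", "_row"],
                             ascending=[True, False, True])
    keep_contig = order.drop_duplicates("contig")["_row"].sort_values().to_numpy()
    report.removed.append(("snp_contig", len(snps) - len(keep_contig)))

    # (ii) greedy windowed LD pruning within chromosome
    dos = genotypes.dosages
    kept: list[int] = []
    n_ld_removed = 0
    sub = snps.iloc[keep_contig].sort_values(["chrom", "pos", "_maf"],
                                             ascending=[True, True, False])
    for chrom, grp in sub.groupby("chrom", sort=False):
        chrom_kept: list[int] = []
        for j in grp["_row"]:
            offending = False
            for k in chrom_kept[-window:]:
                r2 = ld_r2(dos[:, j], dos[:, k])
                if np.isfinite(r2) and r2 > r2_max:
                    offending = True
                    break
            if offending:
                n_ld_removed += 1
            else:
                chrom_kept.append(j)
        kept.extend(chrom_kept)
    report.removed.append(("snp_ld", n_ld_removed))
    kept = sorted(kept)

    # (iii) MAF and missingness on the remaining panel
    maf = genotypes.maf()[kept]
    miss = genotypes.missingness()[kept]
    ok = (maf >= maf_min) & (miss <= miss_max)
    report.removed.append(("snp_maf_miss", int((~ok).sum())))
    final = [kept[i] for i in range(len(kept)) if ok[i]]
    if not final:
        raise ValueError("density reduction removed every SNP")

    ids = genotypes.snps["id"].iloc[final].tolist()
    out = genotypes.subset(snp_ids=ids)
    report.removed.append(("sample_none", 0))
    report.surviving_samples = list(out.samples)
    report.surviving_snps = ids
    report.check_totals()
    return out, report


def random_subsets(genotypes: GenotypeMatrix,
                   sizes: list[int] = (500, 1000, 5000, 10000, 20000),
                   seed: int = 0, nested: bool = True,
                   ) -> dict[int, GenotypeMatrix]:
    """Reproducible random SNP panels of the requested sizes.

    With ``nested=True`` (default) every smaller panel is contained in each
    larger one — a variance-reduction choice for density sweeps; with
    ``nested=False`` each panel is an independent uniform draw.
    """
    rng = np.random.default_rng(seed)
    m = genotypes.n_snps
    too_big = [s for s in sizes if s > m]
    if too_big:
        raise ValueError(f"requested subset size(s) {too_big} exceed panel size {m}")
    ids = genotypes.snps["id"].to_numpy()
    out: dict[int, GenotypeMatrix] = {}
    if nested:
        perm = rng.permutation(m)
        for s in sizes:
            chosen = np.sort(perm[:s])
            out[s] = genotypes.subset(snp_ids=ids[chosen].tolist())
    else:
        for s in sizes:
            chosen = np.sort(rng.choice(m, size=s, replace=False))
            out[s] = genotypes.subset(snp_ids=ids[chosen].tolist())
    return out
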