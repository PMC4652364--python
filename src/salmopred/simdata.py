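"""Synthetic full-sib family populations for testing the analysis pipeline.

The generator emulates a farmed Atlantic salmon breeding design: a batch of
broodstock sires and dams crossed into full-sib families, offspring reared
together and measured for two highly correlated growth traits (weight in g,
length in mm) about one year post-hatching, and everything genotyped on a
dense biallelic SNP panel spread over 29 chromosomes.

Founder haplotypes are drawn per SNP from a configurable minor-allele
frequency distribution; offspring receive recombinant gametes (Poisson
crossover counts per chromosome, uniform positions on the genetic map), so
simulated trios are Mendelian-consistent by construction. Phenotypes invert
the animal model: a polygenic additive genetic value from a set of causal
SNPs, a sex fixed effect, and a correlated environmental deviation. Realized
additive and environmental variances are rescaled exactly to the configured
components (a common scalar per trait, which preserves the configured
correlations), so every replicate simulates the same true heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, Pedigree, PhenotypeTable, UNKNOWN_PARENT


class ConfigError(ValueError):
    """A SimConfig invariant is violated; the message names it."""


@dataclass
class SimConfig:
    """Study design and genetic architecture of a simulated population.

    Defaults reproduce the reference design: 28 sires x 60 dams crossed into
    61 unique full-sib families totalling 534 offspring (at least 6 per
    family), 5,000 SNPs on 29 chromosomes of 1 Morgan each, two polygenic
    traits ("weight": mean 112 g, SD 24 g, h2 = 0.60; "length": mean
    214.1 mm, SD 16.1 mm, h2 = 0.51) with genetic and environmental
    correlations of 0.96 and a modest male-minus-female sex effect of one
    quarter of a phenotypic SD.
    """

    n_sires: int = 28
    n_dams: int = 60
    n_families: int = 61
    total_offspring: int = 534
    min_offspring_per_family: int = 6
    offspring_per_family: list[int] | None = None   # overrides the two above
    n_chromosomes: int = 29
    chromosome_length: float = 1.0                  # Morgans
    n_snps: int = 5000
    n_causal: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)    # uniform MAF sampler
    h2_trait1: float = 0.60
    h2_trait2: float = 0.51
    genetic_corr: float = 0.96
    env_corr: float = 0.96
    trait_names: tuple[str, str] = ("weight", "length")
    trait_mean: tuple[float, float] = (112.0, 214.1)
    trait_sd: tuple[float, float] = (24.0, 16.1)
    sex_effect: tuple[float, float] = (6.0, 4.0)    # added to males, trait units
    causal_chromosomes: list[int] | None = None     # restrict causal SNPs
    qtl_pve: float | None = None                    # single large QTL, fraction of sigma2_a
    mean_contig_snps: float = 2.0                   # contig sizes for density reduction
    n_base_individuals: int = 50                    # broodstock effective size
    n_base_generations: int = 10                    # 0 = founders in linkage equilibrium

    def validate(self) -> None:
        if self.n_snps <= 0:
            raise ConfigError("n_snps must be positive (empty panel rejected)")
        if not (0 < self.n_causal <= self.n_snps):
            raise ConfigError("n_causal must be in [1, n_snps]")
        if self.n_sires <= 0 or self.n_dams <= 0:
            raise ConfigError("n_sires and n_dams must be positive")
        if self.n_families < self.n_sires:
            raise ConfigError("n_families must be >= n_sires (every sire used)")
        if self.n_families > self.n_sires * self.n_dams:
            raise ConfigError("n_families exceeds the number of unique sire-dam pairs")
        for h2 in (self.h2_trait1, self.h2_trait2):
            if not 0.0 <= h2 <= 1.0:
                raise ConfigError("heritabilities must lie in [0, 1]")
        for r in (self.genetic_corr, self.env_corr):
            if not -1.0 <= r <= 1.0:
                raise ConfigError("correlations must lie in [-1, 1] (PSD 2x2 covariance)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_chromosomes <= 0:
            raise ConfigError("n_chromosomes must be positive")
        if self.chromosome_length < 0:
            raise ConfigError("chromosome_length must be non-negative")
        if self.offspring_per_family is not None:
            if len(self.offspring_per_family) != self.n_families:
                raise ConfigError("offspring_per_family length must equal n_families")
            if any(k <= 0 for k in self.offspring_per_family):
                raise ConfigError("offspring_per_family entries must be positive")
        elif self.total_offspring < self.n_families * self.min_offspring_per_family:
            raise ConfigError("total_offspring too small for the per-family minimum")
        if self.qtl_pve is not None and not (0.0 < self.qtl_pve < 1.0):
            raise ConfigError("qtl_pve must lie in (0, 1)")
        if self.n_base_generations < 0 or self.n_base_individuals < 2:
            raise ConfigError("base population needs >=2 individuals, >=0 generations")


@dataclass
class FounderSet:
    """Founder haplotypes plus the SNP map and founder pedigree."""

    haplotypes: np.ndarray          # (n_founders, 2, n_snps) uint8
    snps: pd.DataFrame              # id, chrom, pos, cm, contig, a1, a2
    pedigree: Pedigree
    genetic_pos: np.ndarray         # per-SNP position in Morgans
    chrom_slices: list[slice]


@dataclass
class SimOutput:
    """A complete simulated population."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_breeding_values: pd.DataFrame   # id + one column per trait
    causal_effects: pd.DataFrame         # snp id + per-trait effect sizes

    @property
    def offspring_ids(self) -> list[str]:
        founders = set(self.pedigree.founders)
        return [i for i in self.pedigree.ids if i not in founders]


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimConfig, rng: np.random.Generator) -> FounderSet:
    """Draw founder haplotypes and the SNP map for the configured design."""
    config.validate()
    m = config.n_snps
    counts = [len(a) for a in np.array_split(np.arange(m), config.n_chromosomes)]

    chrom_col, pos_col, gpos_col = [], [], []
    chrom_slices = []
    start = 0
    for c, k in enumerate(counts, start=1):
        frac = np.sort(rng.random(k))
        bp = (frac * 1e8).astype(np.int64) + 1
        bp = np.maximum.accumulate(bp + np.arange(k))  # force strictly increasing
        chrom_col.append(np.full(k, c))
        pos_col.append(bp)
        gpos_col.append(bp / 1e8 * config.chromosome_length)
        chrom_slices.append(slice(start, start + k))
        start += k
    chrom = np.concatenate(chrom_col)
    pos = np.concatenate(pos_col)
    gpos = np.concatenate(gpos_col)

    # contigs: short runs of consecutive SNPs, never spanning chromosomes
    contig = np.empty(m, dtype=object)
    cid = 0
    for sl in chrom_slices:
        j = sl.start
        while j < sl.stop:
            size = int(rng.integers(1, max(2, int(2 * config.mean_contig_snps))))
            for jj in range(j, min(j + size, sl.stop)):
                contig[jj] = f"ctg{cid:06d}"
            cid += 1
            j += size

    snps = pd.DataFrame({
        "id": [f"SNP{j:06d}" for j in range(m)],
        "chrom": chrom.astype(str),
        "pos": pos,
        "cm": gpos * 100.0,
        "contig": contig,
        "a1": "A",
        "a2": "B",
    })

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    n_f = config.n_sires + config.n_dams
    if config.n_base_generations == 0:
        # linkage-equilibrium founders drawn directly from the MAF sampler
        haps = (rng.random((n_f, 2, m)) < freqs).astype(np.uint8)
    else:
        # founders descend from a finite random-mating base population, so
        # their haplotypes carry background LD and low-level relatedness as
        # in a closed broodstock
        haps = _base_population_founders(n_f, freqs, gpos, chrom_slices,
                                         config, rng)

    sire_ids = [f"S{i + 1:03d}" for i in range(config.n_sires)]
    dam_ids = [f"D{i + 1:03d}" for i in range(config.n_dams)]
    ped = Pedigree.from_records(pd.DataFrame({
        "id": sire_ids + dam_ids,
        "sire": UNKNOWN_PARENT,
        "dam": UNKNOWN_PARENT,
        "sex": ["M"] * config.n_sires + ["F"] * config.n_dams,
    }))
    return FounderSet(haplotypes=haps, snps=snps, pedigree=ped,
                      genetic_pos=gpos, chrom_slices=chrom_slices)


def _base_population_founders(n_f: int, freqs: np.ndarray, gpos: np.ndarray,
                              chrom_slices: list[slice], config: SimConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes after generations of finite random mating.

    A pool of ``n_base_individuals`` starts from MAF-sampler haplotypes and
    random-mates for ``n_base_generations``; the founders are then offspring
    of random pool pairs. Drift in the pool builds the within-chromosome LD
    and background relatedness typical of a closed breeding population.
    """
    ne = config.n_base_individuals
    m = len(freqs)
    pool = (rng.random((ne, 2, m)) < freqs).astype(np.uint8)
    L = config.chromosome_length
    for _ in range(config.n_base_generations - 1):
        nxt = np.empty_like(pool)
        for i in range(ne):
            pa, ma = rng.choice(ne, size=2, replace=False)
            nxt[i, 0] = _meiosis(pool[pa], gpos, chrom_slices, L, rng)
            nxt[i, 1] = _meiosis(pool[ma], gpos, chrom_slices, L, rng)
        pool = nxt
    founders = np.empty((n_f, 2, m), dtype=np.uint8)
    for i in range(n_f):
        pa, ma = rng.choice(ne, size=2, replace=False)
        founders[i, 0] = _meiosis(pool[pa], gpos, chrom_slices, L, rng)
        founders[i, 1] = _meiosis(pool[ma], gpos, chrom_slices, L, rng)
    return founders


# ---------------------------------------------------------------------------
# gamete dropping
# ---------------------------------------------------------------------------

def family_plan(config: SimConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Unique (sire index, dam index) pair per family.

    Sires cycle over families so all are used; dams cycle likewise, so with
    the default 61 families from 28 sires and 60 dams a single dam founds
    two families (with different sires).
    """
    pairs = []
    for f in range(config.n_families):
        pairs.append((f % config.n_sires, f % config.n_dams))
    if len(set(pairs)) != len(pairs):
        raise ConfigError("family plan repeats a sire-dam pair")
    return pairs


def _offspring_counts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.offspring_per_family is not None:
        return np.asarray(config.offspring_per_family, dtype=int)
    base = np.full(config.n_families, config.min_offspring_per_family)
    extra = config.total_offspring - base.sum()
    base += rng.multinomial(extra, np.full(config.n_families, 1.0 / config.n_families))
    return base


def _meiosis(parent_haps: np.ndarray, gpos: np.ndarray, chrom_slices: list[slice],
             length: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, m) parental haplotype pair.

    Crossover counts are Poisson(chromosome length in Morgans) with uniform
    positions on the genetic map; ``length = 0`` transmits unrecombined
    parental chromosomes.
    """
    m = parent_haps.shape[1]
    gamete = np.empty(m, dtype=np.uint8)
    for sl in chrom_slices:
        n_co = rng.poisson(length) if length > 0 else 0
        start = int(rng.integers(2))
        if n_co == 0:
            gamete[sl] = parent_haps[start, sl]
            continue
        co_pos = np.sort(rng.uniform(0.0, length, size=n_co))
        idx = np.searchsorted(co_pos, gpos[sl])
        src = (start + idx) % 2
        seg = parent_haps[:, sl]
        gamete[sl] = seg[src, np.arange(sl.stop - sl.start)]
    return gamete


def simulate_offspring(founder: FounderSet, config: SimConfig,
                       rng: np.random.Generator) -> tuple[GenotypeMatrix, Pedigree]:
    """Drop gametes through the family plan; returns all genotyped animals.

    The returned matrix holds founders first, then offspring, and is
    oriented so every SNP counts its minor allele.
    """
    pairs = family_plan(config, rng)
    counts = _offspring_counts(config, rng)
    sire_ids = [i for i in founder.pedigree.ids if i.startswith("S")]
    dam_ids = [i for i in founder.pedigree.ids if i.startswith("D")]

    n_off = int(counts.sum())
    m = founder.haplotypes.shape[2]
    off_geno = np.empty((n_off, m), dtype=np.uint8)
    records = {"id": [], "sire": [], "dam": [], "sex": []}
    k = 0
    for (si, di), n_kids in zip(pairs, counts):
        sire_h = founder.haplotypes[si]
        dam_h = founder.haplotypes[config.n_sires + di]
        for _ in range(n_kids):
            g_s = _meiosis(sire_h, founder.genetic_pos, founder.chrom_slices,
                           config.chromosome_length, rng)
            g_d = _meiosis(dam_h, founder.genetic_pos, founder.chrom_slices,
                           config.chromosome_length, rng)
            off_geno[k] = g_s + g_d
            records["id"].append(f"O{k + 1:04d}")
            records["sire"].append(sire_ids[si])
            records["dam"].append(dam_ids[di])
            records["sex"].append("M" if rng.random() < 0.5 else "F")
            k += 1

    ped = Pedigree.from_records(pd.concat(
        [founder.pedigree.table, pd.DataFrame(records)], ignore_index=True))
    founder_geno = founder.haplotypes.sum(axis=1)
    dosages = np.vstack([founder_geno, off_geno]).astype(float)
    gm = GenotypeMatrix(samples=founder.pedigree.ids + records["id"],
                        snps=founder.snps, dosages=dosages)
    return gm.orient_minor(), ped


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: GenotypeMatrix, pedigree: Pedigree,
                        config: SimConfig, rng: np.random.Generator,
                        ) -> tuple[PhenotypeTable, pd.DataFrame, pd.DataFrame]:
    """Invert the animal model: phenotype = mean + sex + TBV + environment.

    Causal SNPs are sampled without replacement (optionally restricted to
    ``causal_chromosomes``); per-trait effects are bivariate normal with the
    configured genetic correlation. Breeding values and environmental
    deviations are rescaled so their realized variances across phenotyped
    offspring equal h2*sd^2 and (1-h2)*sd^2 exactly.
    """
    config.validate()
    founders = set(pedigree.founders)
    off_ids = [i for i in pedigree.ids if i not in founders]
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    off_idx = np.array([sample_pos[i] for i in off_ids])

    candidates = np.arange(genotypes.n_snps)
    if config.causal_chromosomes is not None:
        allowed = {str(c) for c in config.causal_chromosomes}
        candidates = candidates[genotypes.snps["chrom"].isin(allowed).to_numpy()]
        if len(candidates) < config.n_causal:
            raise ConfigError("not enough SNPs on causal_chromosomes for n_causal")
    causal = np.sort(rng.choice(candidates, size=config.n_causal, replace=False))

    rg = config.genetic_corr
    cov_g = np.array([[1.0, rg], [rg, 1.0]])
    effects = rng.multivariate_normal(np.zeros(2), cov_g, size=config.n_causal,
                                      method="cholesky")
    if config.qtl_pve is not None:
        # first causal SNP carries a share qtl_pve of the additive variance
        effects[0] = np.sign(effects[0]) * 1.0

    W = genotypes.dosages[:, causal].copy()
    col_mean = np.nanmean(W, axis=0)
    nan_mask = np.isnan(W)
    if nan_mask.any():
        W[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    W = W - col_mean

    h2 = np.array([config.h2_trait1, config.h2_trait2])
    sd = np.asarray(config.trait_sd, dtype=float)
    sigma2_a = h2 * sd ** 2
    sigma2_e = (1.0 - h2) * sd ** 2

    if config.qtl_pve is not None:
        tbv_qtl = np.outer(W[:, 0], effects[0])
        tbv_bg = W[:, 1:] @ effects[1:]
        for t in range(2):
            if sigma2_a[t] == 0:
                continue
            vq = tbv_qtl[off_idx, t].var(ddof=1)
            vb = tbv_bg[off_idx, t].var(ddof=1)
            cq = np.sqrt(config.qtl_pve * sigma2_a[t] / vq) if vq > 0 else 0.0
            cb = np.sqrt((1 - config.qtl_pve) * sigma2_a[t] / vb) if vb > 0 else 0.0
            effects[0, t] *= cq
            effects[1:, t] *= cb
        tbv = np.outer(W[:, 0], effects[0]) + W[:, 1:] @ effects[1:]
    else:
        tbv = W @ effects
        for t in range(2):
            v = tbv[off_idx, t].var(ddof=1)
            c = np.sqrt(sigma2_a[t] / v) if (v > 0 and sigma2_a[t] > 0) else 0.0
            effects[:, t] *= c
            tbv[:, t] *= c
    if (sigma2_a == 0).any():
        for t in range(2):
            if sigma2_a[t] == 0:
                effects[:, t] = 0.0
                tbv[:, t] = 0.0

    re_ = config.env_corr
    cov_e = np.array([[1.0, re_], [re_, 1.0]])
    env = rng.multivariate_normal(np.zeros(2), cov_e, size=len(off_ids),
                                  method="cholesky")
    for t in range(2):
        v = env[:, t].var(ddof=1)
        env[:, t] *= np.sqrt(sigma2_e[t] / v) if v > 0 else 0.0

    sex = pedigree.table.set_index("id").loc[off_ids, "sex"].to_numpy()
    male = (sex == "M").astype(float)
    mean = np.asarray(config.trait_mean)
    sex_eff = np.asarray(config.sex_effect)
    y = mean + np.outer(male, sex_eff) + tbv[off_idx] + env

    phen = PhenotypeTable(table=pd.DataFrame({
        "id": off_ids, "sex": sex,
        config.trait_names[0]: y[:, 0],
        config.trait_names[1]: y[:, 1],
    }))
    tbv_df = pd.DataFrame({"id": genotypes.samples,
                           config.trait_names[0]: tbv[:, 0],
                           config.trait_names[1]: tbv[:, 1]})
    eff_df = pd.DataFrame({"snp": genotypes.snps["id"].to_numpy()[causal],
                           config.trait_names[0]: effects[:, 0],
                           config.trait_names[1]: effects[:, 1]})
    return phen, tbv_df, eff_df


def simulate_population(config: SimConfig | None = None,
                        seed: int | np.random.Generator = 0) -> SimOutput:
    """End-to-end simulation: founders, gamete dropping, phenotypes."""
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founder = simulate_founders(config, rng)
    genotypes, pedigree = simulate_offspring(founder, config, rng)
    phen, tbv, eff = simulate_phenotypes(genotypes, pedigree, config, rng)
    return SimOutput(config=config, pedigree=pedigree, genotypes=genotypes,
                     phenotypes=phen, true_breeding_values=tbv, causal_effects=eff)
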