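"""Data containers and plain-text readers/writers.

The pipeline moves three kinds of records around: a pedigree (who are the
sire and dam of each animal), a genotype matrix (biallelic SNP dosages with
per-SNP metadata), and a phenotype table (sex plus the measured traits).
Genotypes travel as PLINK-style PED/MAP text files; pedigrees, phenotypes
and relationship matrices as headered TSV.

Dosages count the *minor* allele at every SNP (ties at frequency 0.5 broken
toward the lexicographically smaller allele), so per-SNP minor allele
frequency is simply ``mean(dosage)/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"
_MISSING_TOKENS = {"0", "", "NA", "na", ".", "nan"}


class FormatError(ValueError):
    """Malformed input file."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree (cycle, duplicate id, missing parent)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents always precede offspring.

    ``table`` has columns ``id, sire, dam, sex`` with ``"0"`` marking an
    unknown parent. Construct via :meth:`from_records` (which sorts and
    validates) rather than directly.
    """

    table: pd.DataFrame

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "Pedigree":
        df = records.copy()
        required = ["id", "sire", "dam"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"pedigree table missing column {col!r}")
        if "sex" not in df.columns:
            df["sex"] = "U"
        for col in ("id", "sire", "dam", "sex"):
            df[col] = df[col].astype(str)
        df.loc[df["sire"].isin(_MISSING_TOKENS), "sire"] = UNKNOWN_PARENT
        df.loc[df["dam"].isin(_MISSING_TOKENS), "dam"] = UNKNOWN_PARENT

        ids = df["id"].tolist()
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate individual id(s): {sorted(set(dup))}")
        known = set(ids)
        order = _topological_order(df, known)
        df = df.set_index("id").loc[order].reset_index()
        return cls(table=df[["id", "sire", "dam", "sex"]])

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        row = self.table.set_index("id").loc[ind]
        sire = None if row["sire"] == UNKNOWN_PARENT else row["sire"]
        dam = None if row["dam"] == UNKNOWN_PARENT else row["dam"]
        return sire, dam

    def parent_indices(self) -> list[tuple[int | None, int | None]]:
        """(sire index, dam index) per individual in table order.

        ``None`` for unknown parents; raises if an individual appears before
        one of its parents (builders must emit topological order).
        """
        pos = {i: k for k, i in enumerate(self.ids)}
        out: list[tuple[int | None, int | None]] = []
        for k, (_, sire, dam, _) in enumerate(self.table.itertuples(index=False)):
            si = pos.get(sire) if sire != UNKNOWN_PARENT else None
            di = pos.get(dam) if dam != UNKNOWN_PARENT else None
            if sire != UNKNOWN_PARENT and (si is None or si >= k):
                raise PedigreeError(f"pedigree not topologically sorted at {self.ids[k]!r}")
            if dam != UNKNOWN_PARENT and (di is None or di >= k):
                raise PedigreeError(f"pedigree not topologically sorted at {self.ids[k]!r}")
            out.append((si, di))
        return out

    @property
    def founders(self) -> list[str]:
        t = self.table
        mask = (t["sire"] == UNKNOWN_PARENT) & (t["dam"] == UNKNOWN_PARENT)
        return t.loc[mask, "id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def _topological_order(df: pd.DataFrame, known: set[str]) -> list[str]:
    """Kahn's algorithm; deterministic (input order), reports one cycle."""
    parents = {}
    for _, row in df.iterrows():
        ps = [p for p in (row["sire"], row["dam"]) if p != UNKNOWN_PARENT and p in known]
        parents[row["id"]] = ps
    children: dict[str, list[str]] = {i: [] for i in parents}
    indeg = {i: 0 for i in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
            indeg[child] += 1
    queue = [i for i in df["id"] if indeg[i] == 0]
    order: list[str] = []
    head = 0
    while head < len(queue):
        node = queue[head]
        head += 1
        order.append(node)
        for c in children[node]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < len(parents):
        cycle = _find_cycle(parents, {i for i in parents if indeg[i] > 0})
        raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
    return order


def _find_cycle(parents: dict[str, list[str]], candidates: set[str]) -> list[str]:
    start = sorted(candidates)[0]
    seen: dict[str, int] = {}
    path = [start]
    node = start
    while node not in seen:
        seen[node] = len(path) - 1
        node = [p for p in parents[node] if p in candidates][0]
        path.append(node)
    return path[seen[node]:]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix.

    ``dosages`` is float with entries in {0, 1, 2} and NaN for missing.
    ``snps`` carries one row per SNP: ``id, chrom, pos, contig, a1, a2``
    where ``a2`` is the counted (minor) allele and ``chrom`` may be the
    string ``"0"`` for SNPs of unknown chromosome.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNP
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset(self, samples: list[str] | None = None,
               snp_ids: list[str] | None = None) -> "GenotypeMatrix":
        dos = self.dosages
        samp = self.samples
        snps = self.snps
        if samples is not None:
            pos = {s: i for i, s in enumerate(self.samples)}
            missing = [s for s in samples if s not in pos]
            if missing:
                raise KeyError(f"unknown sample id(s): {missing[:5]}")
            idx = [pos[s] for s in samples]
            dos = dos[idx, :]
            samp = list(samples)
        if snp_ids is not None:
            pos = {s: i for i, s in enumerate(self.snps["id"])}
            missing = [s for s in snp_ids if s not in pos]
            if missing:
                raise KeyError(f"unknown SNP id(s): {missing[:5]}")
            jdx = [pos[s] for s in snp_ids]
            dos = dos[:, jdx]
            snps = self.snps.iloc[jdx].reset_index(drop=True)
        return GenotypeMatrix(samples=samp, snps=snps, dosages=dos.copy())

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip SNPs so the counted allele is the minor one.

        Ties at frequency 0.5 keep the lexicographically smaller allele as
        the counted allele, matching the PED reader's convention.
        """
        dos = self.dosages.copy()
        snps = self.snps.copy()
        counts = np.nansum(dos, axis=0)
        called = 2 * np.sum(~np.isnan(dos), axis=0)
        a1 = snps["a1"].to_numpy(dtype=object)
        a2 = snps["a2"].to_numpy(dtype=object)
        flip = (2 * counts > called) | ((2 * counts == called) & (a1 < a2))
        dos[:, flip] = 2.0 - dos[:, flip]
        snps.loc[flip, ["a1", "a2"]] = snps.loc[flip, ["a2", "a1"]].to_numpy()
        return GenotypeMatrix(samples=list(self.samples), snps=snps, dosages=dos)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-individual sex and trait measurements (NaN = not measured)."""

    table: pd.DataFrame  # columns: id, sex, then one column per trait

    def __post_init__(self) -> None:
        for col in ("id", "sex"):
            if col not in self.table.columns:
                raise FormatError(f"phenotype table missing column {col!r}")
        self.table = self.table.copy()
        self.table["id"] = self.table["id"].astype(str)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("id", "sex")]

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def check_ids(self, reference_ids: list[str] | set[str],
                  label: str = "pedigree") -> list[str]:
        """Return ids absent from ``reference_ids``; warn when non-empty."""
        ref = set(reference_ids)
        unmatched = [i for i in self.ids if i not in ref]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} phenotyped id(s) not found in {label}: "
                f"{unmatched[:10]}", stacklevel=2)
        return unmatched


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def read_plink(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read whitespace-delimited PED + MAP into a minor-allele dosage matrix.

    Each SNP is recoded to a dosage of its minor allele (ties at 0.5 broken
    toward the lexicographically smaller allele); ``0 0`` genotypes become
    NaN. MAP columns are chromosome, SNP id, genetic position (cM), bp.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str})
    m = len(map_df)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * m} for {m} MAP SNPs")
            samples.append(fields[1])
            rows.append(np.array(fields[6:], dtype=object))
    if not rows:
        raise FormatError(f"{ped_path}: no genotype records")

    alleles = np.stack(rows)                       # (n, 2m)
    a_one = alleles[:, 0::2]
    a_two = alleles[:, 1::2]
    n = len(samples)
    dosages = np.full((n, m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = np.stack([a_one[:, j], a_two[:, j]], axis=1)
        obs = col[(col != "0").all(axis=1)]
        uniq, counts = np.unique(obs, return_counts=True)
        uniq = [u for u in uniq]
        if len(uniq) == 0:
            a1_list.append("0"); a2_list.append("0")
            continue
        if len(uniq) == 1:
            minor, major = "0", uniq[0]
        elif len(uniq) == 2:
            c = dict(zip(uniq, counts))
            ordered = sorted(uniq, key=lambda a: (c[a], a))  # rarer first, ties alphabetical
            minor, major = ordered[0], ordered[1]
        else:
            raise FormatError(f"SNP {map_df['id'][j]!r} has >2 alleles: {uniq}")
        missing = (col == "0").any(axis=1)
        dosages[~missing, j] = (col[~missing] == minor).sum(axis=1)
        if minor == "0":
            dosages[~missing, j] = 0.0
        a1_list.append(major); a2_list.append(minor)

    snps = map_df.copy()
    snps["contig"] = snps["id"]
    snps["a1"] = a1_list
    snps["a2"] = a2_list
    return GenotypeMatrix(samples=samples,
                          snps=snps[["id", "chrom", "pos", "cm", "contig", "a1", "a2"]],
                          dosages=dosages)


def write_plink(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path,
                pedigree: Pedigree | None = None) -> None:
    """Write PED/MAP. Dosage d becomes d copies of allele a2 and 2-d of a1."""
    snps = gm.snps
    cm = snps["cm"] if "cm" in snps.columns else pd.Series(np.zeros(len(snps)))
    with open(map_path, "w") as fh:
        for chrom, sid, c, pos in zip(snps["chrom"], snps["id"], cm, snps["pos"]):
            fh.write(f"{chrom}\t{sid}\t{c:g}\t{int(pos)}\n")

    meta = {}
    if pedigree is not None:
        for _, row in pedigree.table.iterrows():
            sex_code = {"M": "1", "F": "2"}.get(row["sex"], "0")
            meta[row["id"]] = (row["sire"], row["dam"], sex_code)
    a1 = snps["a1"].to_numpy(dtype=object)
    a2 = snps["a2"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            sire, dam, sex = meta.get(sample, ("0", "0", "0"))
            fields = ["FAM", sample, sire, dam, sex, "-9"]
            row = gm.dosages[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree.from_records(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str})
    return PhenotypeTable(table=df)


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    pt.table.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a symmetric matrix TSV with id header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.index.tolist(), df.to_numpy(dtype=float)


def write_matrix_tsv(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")
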