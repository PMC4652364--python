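"""Pedigree (A) and genomic (G) relationship matrices.

A is the numerator relationship matrix from the tabular method: for an
individual i with parents s and d, A_ij = (A_js + A_jd)/2 for previously
processed j, and A_ii = 1 + A_sd/2 (the diagonal is one plus the inbreeding
coefficient). G follows VanRaden's first method,

    G = W W' / (2 * sum_k p_k (1 - p_k)),   W = M - 2p,

with M the dosage matrix and p the allele frequencies used for centering.
Both matrices serve as the covariance structure of the additive genetic
effect in the animal model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Symmetric kinship-scale matrix over a fixed set of individuals."""

    kind: str                # "A" or "G"
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric (tol 1e-10)")

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(kind=self.kind, ids=list(ids),
                                  values=self.values[np.ix_(idx, idx)])

    def coefficient(self, a: str, b: str) -> float:
        pos = {s: i for i, s in enumerate(self.ids)}
        return float(self.values[pos[a], pos[b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    Requires (and checks) that the pedigree is topologically sorted;
    unknown parents contribute zero relationship.
    """
    parents = pedigree.parent_indices()  # raises if unsorted
    n = len(parents)
    A = np.zeros((n, n))
    for i, (s, d) in enumerate(parents):
        row = np.zeros(i)
        if s is not None:
            row += 0.5 * A[s, :i]
        if d is not None:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        inb = 0.5 * A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + inb
    return RelationshipMatrix(kind="A", ids=pedigree.ids, values=A)


def g_matrix_vanraden(genotypes: GenotypeMatrix,
                      freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``freqs`` defaults to observed sample allele frequencies of the counted
    allele. Missing dosages are mean-imputed (to 2p) before centering, which
    is unbiased at the mean. SNPs monomorphic at the supplied frequencies
    carry no information and are dropped with a warning.
    """
    dos = genotypes.dosages.astype(float).copy()
    if freqs is None:
        freqs = genotypes.allele_freq()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_snps,):
        raise ValueError("freqs length must equal the SNP count")

    poly = (freqs > 0.0) & (freqs < 1.0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    if (~poly).any():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic SNP(s) from G",
                      stacklevel=2)
        dos = dos[:, poly]
        freqs = freqs[poly]

    nan_mask = np.isnan(dos)
    if nan_mask.any():
        fill = 2.0 * freqs
        dos[nan_mask] = np.take(fill, np.where(nan_mask)[1])
    W = dos - 2.0 * freqs
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(kind="G", ids=list(genotypes.samples), values=G)


def invert_relationship(matrix: RelationshipMatrix | np.ndarray,
                        ridge: float = 1e-6,
                        max_ridge: float = 1e-2) -> np.ndarray:
    """Invert a relationship matrix, ridging the diagonal if singular.

    Tries the raw Cholesky inverse first; on failure (or an inaccurate
    inverse) adds ``ridge`` to the diagonal, escalating tenfold up to
    ``max_ridge``. The applied ridge is logged. Raises if the matrix is
    still numerically singular at ``max_ridge``.
    """
    M = matrix.values if isinstance(matrix, RelationshipMatrix) else np.asarray(matrix)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    n = M.shape[0]
    eye = np.eye(n)

    def _try(mat: np.ndarray) -> np.ndarray | None:
        try:
            L = np.linalg.cholesky(mat)
        except np.linalg.LinAlgError:
            return None
        Linv = np.linalg.solve(L, eye)
        inv = Linv.T @ Linv
        if np.max(np.abs(mat @ inv - eye)) > 1e-6:
            return None
        return inv

    inv = _try(M)
    if inv is not None:
        return inv
    r = ridge
    while r <= max_ridge * (1 + 1e-12):
        inv = _try(M + r * eye)
        if inv is not None:
            logger.info("relationship matrix singular; applied ridge %.1e", r)
            return inv
        r *= 10.0
    raise np.linalg.LinAlgError(
        f"matrix still singular after ridge {max_ridge:g}")
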