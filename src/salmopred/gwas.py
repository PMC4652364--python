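"""Two-step mixed-model association (GRAMMAR-style score test) and
follow-up SNP effect / variance-explained estimation.

Step one fits the polygenic animal model once (see :mod:`salmopred.varcomp`)
with the genomic relationship matrix, fixing the phenotypic covariance
V = sigma2_a K + sigma2_e I. Step two score-tests each SNP: with the
fixed-effect projection

    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

the statistic for a centered dosage vector g is T = (g'Py)^2 / (g'Pg),
chi-square with 1 df under the null — the family-based "mmscore" form that
accounts for relatedness through V.

Genome-wide and per-chromosome significance thresholds use Bonferroni
correction 0.05/N. Follow-up effects refit the genotype as a three-class
fixed effect by GLS under the same V: the additive effect alpha is half the
difference between the two homozygote means, the dominance effect delta is
the heterozygote deviation from the homozygote midpoint, and the
proportion of additive genetic variance explained is

    PVE = 2pq (alpha + delta (q - p))^2 / V_A,

with the delta term dropped for SNPs showing only two genotype classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .varcomp import AnimalModelSpec, VarianceComponents

logger = logging.getLogger(__name__)

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / N."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


@dataclass
class GwasResult:
    """Per-SNP score statistics with multiplicity thresholds."""

    table: pd.DataFrame                 # snp, chrom, stat, p
    genomewide_threshold: float
    chrom_thresholds: dict[str, float]
    lambda_gc: float
    n_tests: int
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def significant(self, level: str = "genomewide") -> pd.DataFrame:
        t = self.table
        if level == "genomewide":
            return t[t["p"] < self.genomewide_threshold]
        thr = t["chrom"].map(self.chrom_thresholds)
        return t[t["p"] < thr]


def grammar_scan(model: AnimalModelSpec, vc: VarianceComponents,
                 genotypes: GenotypeMatrix, alpha: float = 0.05) -> GwasResult:
    """Mixed-model score test of every polymorphic SNP.

    ``genotypes`` must cover the model's record ids; monomorphic SNPs are
    skipped with a reason. Thresholds are Bonferroni at ``alpha`` over the
    tested SNP count (genome-wide) and per-chromosome counts.
    """
    gm = genotypes.subset(samples=model.ids)
    K = model.k_sub()
    n = len(model.y)
    V = vc.sigma2_a * K + vc.sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    Vi_X = Vi @ model.X
    XtViX = model.X.T @ Vi_X
    if np.linalg.cond(XtViX) > 1e12:
        raise np.linalg.LinAlgError("X' V^-1 X is singular")
    P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    Py = P @ model.y

    D = gm.dosages.astype(float).copy()
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    mono = np.nanstd(D, axis=0) == 0
    D = D - D.mean(axis=0)

    num = (D.T @ Py) ** 2
    den = np.einsum("ij,ij->j", D, P @ D)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(mono | (den <= 0), np.nan, num / np.maximum(den, 1e-300))
    pvals = stats.chi2.sf(stat, df=1)

    snps = gm.snps
    tested = ~np.isnan(stat)
    skipped = [(snps["id"].iloc[j], "monomorphic")
               for j in np.where(~tested)[0]]
    if skipped:
        logger.info("skipped %d untestable SNP(s)", len(skipped))
    table = pd.DataFrame({
        "snp": snps["id"].to_numpy()[tested],
        "chrom": snps["chrom"].to_numpy()[tested],
        "stat": stat[tested],
        "p": pvals[tested],
    }).reset_index(drop=True)

    n_tests = int(tested.sum())
    chrom_counts = table["chrom"].value_counts()
    chrom_thr = {c: bonferroni(alpha, int(k)) for c, k in chrom_counts.items()}
    lam = genomic_inflation(table["p"].to_numpy()) if n_tests else float("nan")
    return GwasResult(table=table,
                      genomewide_threshold=bonferroni(alpha, n_tests),
                      chrom_thresholds=chrom_thr, lambda_gc=lam,
                      n_tests=n_tests, skipped=skipped)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi-square (1 df) over the
    null median 0.4549; ~1 for a calibrated test."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        logger.warning("genomic inflation estimated from only %d tests", len(p))
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_MEDIAN_1DF)


def qq_data(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a Q-Q plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"expected": -np.log10(expected),
                         "observed": -np.log10(np.clip(p, 1e-300, 1.0))})


@dataclass
class SnpEffectRecord:
    """Follow-up fixed-SNP fit: allele frequencies, alpha/delta, PVE."""

    marker: str
    p_major: float
    q_minor: float
    alpha: float
    se_alpha: float
    delta: float | None
    se_delta: float | None
    n_classes: int
    pve_fraction: float | None = None

    def as_dict(self) -> dict:
        return {"marker": self.marker, "p": self.p_major, "q": self.q_minor,
                "alpha": self.alpha, "se_alpha": self.se_alpha,
                "delta": self.delta, "se_delta": self.se_delta,
                "n_classes": self.n_classes, "pve": self.pve_fraction}


def snp_effect_fit(model: AnimalModelSpec, vc: VarianceComponents,
                   dosage: np.ndarray, marker: str = "") -> SnpEffectRecord:
    """GLS fit of genotype-class means jointly with sex under V.

    With all three classes observed: alpha = (mean_majorhom - mean_minorhom)/2
    and delta = mean_het - midpoint of the homozygotes. With only two
    classes delta is undefined and omitted; alpha is then the allele
    substitution slope from an additive (dosage) fit.
    """
    g = np.asarray(dosage, dtype=float)
    obs = ~np.isnan(g)
    if obs.sum() < len(g):
        logger.info("%d record(s) missing the SNP genotype dropped", int((~obs).sum()))
    y = model.y[obs]
    g = g[obs]
    classes = np.unique(g)
    if len(classes) < 2:
        raise ValueError("SNP has a single observed genotype class")

    K = model.k_sub()[np.ix_(obs, obs)]
    n = len(y)
    V = vc.sigma2_a * K + vc.sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)

    # non-genotype fixed effects, centered so class means are sex-adjusted
    Xf = model.X.copy()[obs]
    is_const = Xf.std(axis=0) == 0
    covars = Xf[:, ~is_const]
    covars = covars - covars.mean(axis=0)

    q_minor = float(g.mean() / 2.0)        # dosage counts the minor allele
    p_major = 1.0 - q_minor

    if len(classes) == 3:
        Xg = np.column_stack([(g == c).astype(float) for c in (0.0, 1.0, 2.0)])
        X = np.hstack([Xg, covars])
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        C = np.linalg.inv(XtViX)
        m0, m1, m2 = beta[:3]              # major hom, het, minor hom means
        c_alpha = np.zeros(X.shape[1]); c_alpha[0], c_alpha[2] = 0.5, -0.5
        c_delta = np.zeros(X.shape[1]); c_delta[1] = 1.0
        c_delta[0] = c_delta[2] = -0.5
        alpha = float(m0 - m2) / 2.0
        delta = float(m1 - (m0 + m2) / 2.0)
        se_alpha = float(np.sqrt(c_alpha @ C @ c_alpha))
        se_delta = float(np.sqrt(c_delta @ C @ c_delta))
        return SnpEffectRecord(marker=marker, p_major=p_major, q_minor=q_minor,
                               alpha=alpha, se_alpha=se_alpha, delta=delta,
                               se_delta=se_delta, n_classes=3)

    X = np.hstack([np.ones((n, 1)), g[:, None], covars])
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    C = np.linalg.inv(XtViX)
    return SnpEffectRecord(marker=marker, p_major=p_major, q_minor=q_minor,
                           alpha=float(beta[1]), se_alpha=float(np.sqrt(C[1, 1])),
                           delta=None, se_delta=None, n_classes=2)


def pve(p: float, q: float, alpha: float, delta: float | None,
        v_a: float, n_classes: int = 3) -> float:
    """Proportion of additive genetic variance explained by one SNP:
    2pq (alpha + delta (q - p))^2 / V_A, the delta term dropped when only
    two genotype classes were observed."""
    if v_a <= 0:
        raise ValueError("V_A must be positive")
    if abs(p + q - 1.0) > 1e-8:
        raise ValueError("allele frequencies must satisfy p + q = 1")
    if delta is None or n_classes == 2:
        delta = 0.0
    return float(2.0 * p * q * (alpha + delta * (q - p)) ** 2 / v_a)
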