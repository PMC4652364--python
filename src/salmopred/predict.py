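"""BLUP breeding-value prediction and cross-validated accuracy.

Breeding values solve Henderson's mixed-model equations for the animal
model with either the pedigree (PBLUP) or genomic (GBLUP) relationship
matrix as the covariance of the animal effect:

    [ X'X      X'Z          ] [b]   [X'y]
    [ Z'X      Z'Z + K^-1 l ] [u] = [Z'y],    l = sigma2_e / sigma2_a.

Masked (validation) individuals keep their row in K but contribute no
record, so their EBVs are predicted purely through relationships. Accuracy
follows the cross-validation convention r(EBV, y) / h with h the square
root of the full-data heritability estimate under the same relationship
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix, invert_relationship
from .varcomp import AnimalModelSpec, VarianceComponents, heritability, reml_fit

logger = logging.getLogger(__name__)


def blup_ebv(model: AnimalModelSpec, vc: VarianceComponents,
             masked_ids: list[str] | set[str] = (),
             kinv: np.ndarray | None = None) -> pd.Series:
    """Solve the mixed-model equations; EBVs for every individual in K.

    Records of ``masked_ids`` are excluded from the right-hand side (their
    phenotypes never enter the solve); their breeding values are predicted
    through the relationship matrix. ``kinv`` may be supplied to reuse a
    precomputed inverse across folds.
    """
    masked = set(masked_ids)
    keep = np.array([i not in masked for i in model.ids])
    if not keep.any():
        raise ValueError("no training records left after masking")
    y = model.y[keep]
    X = model.X[keep]
    train_ids = [i for i, k in zip(model.ids, keep) if k]

    all_ids = model.K.ids
    pos = {s: i for i, s in enumerate(all_ids)}
    n_all = len(all_ids)
    t = len(y)
    Z = np.zeros((t, n_all))
    Z[np.arange(t), [pos[i] for i in train_ids]] = 1.0

    if kinv is None:
        kinv = invert_relationship(model.K)
    lam = vc.sigma2_e / vc.sigma2_a if vc.sigma2_a > 0 else np.inf
    if not np.isfinite(lam):
        raise ValueError("sigma2_a = 0: breeding values are identically zero")

    p = X.shape[1]
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + kinv * lam])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"mixed-model equations singular (fixed block {p}x{p}, "
            f"animal block {n_all}x{n_all})") from exc
    return pd.Series(sol[p:], index=all_ids, name="ebv")


@dataclass
class CvAccuracy:
    """Per-fold cross-validation accuracies plus the h used per method."""

    table: pd.DataFrame        # method, density, replicate, fold, accuracy
    h2_used: dict[str, float]  # method -> full-data h2 in the denominator

    def replicate_means(self) -> pd.DataFrame:
        return (self.table.groupby(["method", "density", "replicate"])["accuracy"]
                .mean().reset_index())

    def summary(self) -> pd.DataFrame:
        reps = self.replicate_means()
        return (reps.groupby(["method", "density"])["accuracy"]
                .agg(mean="mean", sd="std").reset_index())


def _partitions(ids: list[str], k: int, reps: int,
                rng: np.random.Generator) -> list[list[list[str]]]:
    """reps random k-partitions; the first (n mod k) folds get the extra."""
    n = len(ids)
    base, extra = divmod(n, k)
    sizes = [base + (1 if f < extra else 0) for f in range(k)]
    out = []
    for _ in range(reps):
        perm = rng.permutation(n)
        folds, start = [], 0
        for sz in sizes:
            folds.append([ids[j] for j in perm[start:start + sz]])
            start += sz
        out.append(folds)
    return out


def _cv_once(model: AnimalModelSpec, vc: VarianceComponents, h: float,
             partitions: list[list[list[str]]], method: str, density,
             refit_vc: bool = False) -> pd.DataFrame:
    kinv = invert_relationship(model.K)
    y_by_id = dict(zip(model.ids, model.y))
    rows = []
    for rep, folds in enumerate(partitions, start=1):
        for f, fold in enumerate(folds, start=1):
            if refit_vc:
                keep = [i for i in model.ids if i not in set(fold)]
                sub = AnimalModelSpec(
                    y=np.array([y_by_id[i] for i in keep]),
                    X=model.X[[i in set(keep) for i in model.ids]],
                    ids=keep, K=model.K)
                vc_fold = reml_fit(sub)
            else:
                vc_fold = vc
            ebv = blup_ebv(model, vc_fold, masked_ids=fold, kinv=kinv)
            y_val = np.array([y_by_id[i] for i in fold])
            if y_val.std() == 0:
                logger.warning("fold %d/%d has zero phenotype variance; skipped",
                               rep, f)
                continue
            r = np.corrcoef(ebv.loc[fold].to_numpy(), y_val)[0, 1]
            rows.append({"method": method, "density": density,
                         "replicate": rep, "fold": f, "accuracy": r / h})
    return pd.DataFrame(rows)


def cross_validate(model: AnimalModelSpec, vc: VarianceComponents | None = None,
                   k: int = 5, reps: int = 5, seed: int = 0,
                   method: str | None = None, density="full",
                   refit_vc: bool = False) -> CvAccuracy:
    """k-fold cross-validated prediction accuracy r(EBV, y)/h.

    Folds partition the phenotyped records (unphenotyped relatives stay in
    K and transmit information); ``h`` is the square root of the full-data
    REML heritability under the same relationship matrix. Identical seed
    gives identical partitions and accuracies.
    """
    if len(model.ids) < k:
        raise ValueError("fewer phenotyped records than folds")
    if vc is None:
        vc = reml_fit(model)
    h2, _ = heritability(vc)
    if h2 <= 0:
        raise ValueError("non-positive heritability: accuracy undefined")
    h = float(np.sqrt(h2))
    method = method or ("GBLUP" if model.K.kind == "G" else "PBLUP")
    rng = np.random.default_rng(seed)
    parts = _partitions(model.ids, k, reps, rng)
    table = _cv_once(model, vc, h, parts, method, density, refit_vc=refit_vc)
    return CvAccuracy(table=table, h2_used={method: h2})


def density_sweep(phenotypes, pedigree, genotypes, trait: str,
                  sizes: list[int] = (500, 1000, 5000, 10000, 20000),
                  k: int = 5, reps: int = 5, seed: int = 0,
                  nested: bool = True) -> CvAccuracy:
    """GBLUP accuracy across marker densities, with PBLUP as the baseline.

    The pedigree predictor ignores markers, so PBLUP is computed once; the
    genomic relationship matrix is rebuilt per density panel. All methods
    and densities reuse the same fold partitions (paired comparison), and
    each method uses a single accuracy denominator h — from the full-panel
    G-REML fit for GBLUP and the A-REML fit for PBLUP — so the sweep
    compares predictive correlations, not per-panel heritability noise.
    """
    from .qc import random_subsets
    from .relmat import a_matrix, g_matrix_vanraden
    from .varcomp import make_model

    A = a_matrix(pedigree)
    model_a = make_model(phenotypes, A, trait)
    vc_a = reml_fit(model_a)
    h2_a, _ = heritability(vc_a)
    rng = np.random.default_rng(seed)
    parts = _partitions(model_a.ids, k, reps, rng)

    tables = [_cv_once(model_a, vc_a, float(np.sqrt(h2_a)), parts,
                       "PBLUP", "any")]
    h2_used = {"PBLUP": h2_a}

    panels = random_subsets(genotypes, sizes=list(sizes), seed=seed, nested=nested)
    panels["full"] = genotypes
    G_full = g_matrix_vanraden(genotypes)
    vc_full = reml_fit(make_model(phenotypes, G_full, trait))
    h2_full, _ = heritability(vc_full)
    h_g = float(np.sqrt(h2_full))
    h2_used["GBLUP"] = h2_full
    for density, panel in panels.items():
        G = g_matrix_vanraden(panel)
        model_g = make_model(phenotypes, G, trait)
        vc_g = reml_fit(model_g)
        tables.append(_cv_once(model_g, vc_g, h_g, parts, "GBLUP", density))
    return CvAccuracy(table=pd.concat(tables, ignore_index=True), h2_used=h2_used)


def plot_density_sweep(cv: CvAccuracy, path: str) -> None:
    """Accuracy vs marker density, one line per method (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = cv.summary()
    fig, ax = plt.subplots(figsize=(6, 4))
    gb = summ[summ["method"] == "GBLUP"].copy()
    order = sorted([d for d in gb["density"] if d != "full"],
                   key=lambda v: float(v)) + (["full"] if "full" in set(gb["density"]) else [])
    gb = gb.set_index("density").loc[order]
    ax.errorbar(range(len(gb)), gb["mean"], yerr=gb["sd"], marker="o", label="GBLUP")
    pb = summ[summ["method"] == "PBLUP"]
    if len(pb):
        ax.axhline(float(pb["mean"].iloc[0]), color="gray", ls="--", label="PBLUP")
    ax.set_xticks(range(len(gb)), [str(d) for d in gb.index])
    ax.set_xlabel("marker density (SNPs)")
    ax.set_ylabel("accuracy r(EBV, y)/h")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
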