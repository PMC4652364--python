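"""REML variance components for the single-random-effect animal model.

The model is y = Xb + u + e with u ~ N(0, K sigma2_a) and
e ~ N(0, I sigma2_e), K a relationship matrix (pedigree A or genomic G)
restricted to the phenotyped individuals (one record each, so the marginal
covariance of y is K sigma2_a + I sigma2_e). Narrow-sense heritability is
h2 = sigma2_a / (sigma2_a + sigma2_e).

The fit eigendecomposes K once, rotates y and X into the eigenbasis where
the covariance is diagonal, profiles out the residual variance, and
maximizes the restricted likelihood over the single variance ratio
gamma = sigma2_a / sigma2_e by bounded Brent search on log10(gamma) — exact
for this model class and far cheaper than a general AI-REML iteration.
Standard errors come from the observed information (numerical Hessian of
the restricted log-likelihood at the optimum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genio import PhenotypeTable
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

_LOG10_BOUNDS = (-8.0, 8.0)


class NonIdentifiableError(RuntimeError):
    """K is (numerically) proportional to the identity: the additive and
    residual variances are not separately identifiable (flat likelihood
    ridge along sigma2_a + sigma2_e = const)."""


@dataclass
class AnimalModelSpec:
    """Aligned inputs of the animal model for one trait.

    ``ids`` names the record-level individuals (rows of ``y`` and ``X``);
    they must all be present in ``K.ids``. ``K`` may cover extra,
    unphenotyped individuals (parents) — REML restricts to the record set,
    BLUP prediction uses the full matrix.
    """

    y: np.ndarray
    X: np.ndarray
    ids: list[str]
    K: RelationshipMatrix
    x_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        n = len(self.y)
        if self.X.shape[0] != n or len(self.ids) != n:
            raise ValueError("rows of y, X and ids must align")
        missing = set(self.ids) - set(self.K.ids)
        if missing:
            raise ValueError(f"record id(s) absent from K: {sorted(missing)[:5]}")
        # drop aliased fixed-effect columns so X has full column rank
        q, r = np.linalg.qr(self.X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
        if not keep.all():
            dropped = [i for i, k in enumerate(keep) if not k]
            logger.info("dropping %d aliased fixed-effect column(s): %s",
                        len(dropped), dropped)
            self.X = self.X[:, keep]
            if self.x_names:
                self.x_names = [nm for nm, k in zip(self.x_names, keep) if k]

    def k_sub(self) -> np.ndarray:
        return self.K.subset(self.ids).values


def make_model(phenotypes: PhenotypeTable, K: RelationshipMatrix,
               trait: str) -> AnimalModelSpec:
    """Build the intercept+sex animal model for one trait.

    Records with a missing trait value or absent from K are dropped (with a
    logged count).
    """
    t = phenotypes.table
    if trait not in t.columns:
        raise KeyError(f"unknown trait {trait!r}")
    in_k = t["id"].isin(set(K.ids))
    has_y = t[trait].notna()
    dropped = int((~(in_k & has_y)).sum())
    if dropped:
        logger.info("dropping %d record(s) without genotype/relationship or trait",
                    dropped)
    t = t[in_k & has_y]
    male = (t["sex"] == "M").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(t)), male])
    return AnimalModelSpec(y=t[trait].to_numpy(), X=X, ids=t["id"].tolist(),
                           K=K, x_names=["intercept", "sex_male"])


@dataclass
class VarianceComponents:
    """REML estimates of (sigma2_a, sigma2_e) and their uncertainty."""

    sigma2_a: float
    sigma2_e: float
    se_a: float
    se_e: float
    cov_ae: float
    loglik: float
    converged: bool
    boundary: bool
    n_iter: int

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_e


def _profile_loglik(log10_gamma: float, s: np.ndarray, yt: np.ndarray,
                    Xt: np.ndarray) -> tuple[float, float]:
    """Restricted log-likelihood profiled over sigma2_e, at a fixed ratio.

    Returns (loglik up to an additive constant, profiled sigma2_e).
    """
    gamma = 10.0 ** log10_gamma
    w = gamma * s + 1.0                       # V / sigma2_e, diagonal
    n, p = Xt.shape
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    rss = float(r @ (r / w))
    sigma2_e = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(sigma2_e) + np.log(w).sum()
                 + logdet_xwx + (n - p))
    return ll, sigma2_e


def restricted_loglik(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                      sigma2_a: float, sigma2_e: float) -> float:
    """Restricted log-likelihood at given components (dense, up to const)."""
    n, p = X.shape
    V = sigma2_a * K + sigma2_e * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(V)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    _, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (logdet_v + logdet_x + quad)


def reml_fit(model: AnimalModelSpec, tol: float = 1e-10) -> VarianceComponents:
    """Fit the animal model by eigen-rotated REML.

    Raises :class:`NonIdentifiableError` when K has no eigenvalue spread
    (e.g. K = I), in which case only the total variance is estimable.
    """
    K = model.k_sub()
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    if s.max() <= 0:
        raise ValueError("K has no positive eigenvalue")
    if (s.max() - s.min()) / s.max() < 1e-8:
        raise NonIdentifiableError(
            "relationship matrix is proportional to the identity; "
            "sigma2_a and sigma2_e lie on a flat likelihood ridge")

    yt = U.T @ model.y
    Xt = U.T @ model.X

    neg = lambda lg: -_profile_loglik(lg, s, yt, Xt)[0]
    res = optimize.minimize_scalar(neg, bounds=_LOG10_BOUNDS, method="bounded",
                                   options={"xatol": 1e-10})
    lg = float(res.x)
    ll, sigma2_e = _profile_loglik(lg, s, yt, Xt)
    gamma = 10.0 ** lg
    sigma2_a = gamma * sigma2_e

    boundary = (lg - _LOG10_BOUNDS[0] < 1e-3) or (_LOG10_BOUNDS[1] - lg < 1e-3)
    converged = bool(res.success)
    if not converged:
        logger.warning("REML 1-D search did not converge: %s", res.message)

    # observed information in (sigma2_a, sigma2_e) via the rotated loglik
    def ll_ab(a: float, e: float) -> float:
        v = a * s + e
        if np.any(v <= 0):
            return -np.inf
        Xw = Xt / v[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        _, logdet_x = np.linalg.slogdet(XtWX)
        return -0.5 * (np.log(v).sum() + logdet_x + float(r @ (r / v)))

    se_a = se_e = cov_ae = np.nan
    if not boundary:
        ha = max(sigma2_a, 1e-8) * 1e-4
        he = max(sigma2_e, 1e-8) * 1e-4
        f = ll_ab
        a0, e0 = sigma2_a, sigma2_e
        daa = (f(a0 + ha, e0) - 2 * f(a0, e0) + f(a0 - ha, e0)) / ha ** 2
        dee = (f(a0, e0 + he) - 2 * f(a0, e0) + f(a0, e0 - he)) / he ** 2
        dae = (f(a0 + ha, e0 + he) - f(a0 + ha, e0 - he)
               - f(a0 - ha, e0 + he) + f(a0 - ha, e0 - he)) / (4 * ha * he)
        info = -np.array([[daa, dae], [dae, dee]])
        try:
            cov = np.linalg.inv(info)
            if cov[0, 0] > 0 and cov[1, 1] > 0:
                se_a = float(np.sqrt(cov[0, 0]))
                se_e = float(np.sqrt(cov[1, 1]))
                cov_ae = float(cov[0, 1])
        except np.linalg.LinAlgError:
            pass
    if boundary:
        logger.info("REML estimate at parameter boundary (log10 gamma = %.2f)", lg)

    return VarianceComponents(sigma2_a=sigma2_a, sigma2_e=sigma2_e,
                              se_a=se_a, se_e=se_e, cov_ae=cov_ae,
                              loglik=float(ll), converged=converged,
                              boundary=boundary,
                              n_iter=int(res.nfev))


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """h2 = sigma2_a / sigma2_p with a delta-method standard error."""
    sp = vc.sigma2_p
    if sp <= 0:
        raise ValueError("sigma2_p must be positive for heritability")
    h2 = vc.sigma2_a / sp
    if np.isfinite(vc.se_a) and np.isfinite(vc.se_e):
        g = np.array([vc.sigma2_e, -vc.sigma2_a]) / sp ** 2
        C = np.array([[vc.se_a ** 2, vc.cov_ae], [vc.cov_ae, vc.se_e ** 2]])
        se = float(np.sqrt(max(g @ C @ g, 0.0)))
    else:
        se = float("nan")
    return float(h2), se
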