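"""Single-SNP linear mixed-model association (GEMMA-style).

The null model ``y = X b + u + e`` with ``u ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)`` is fitted by REML using the standard efficient
trick: one eigendecomposition of the kinship matrix rotates the model to a
diagonal covariance, leaving a 1-D optimization over the variance ratio
``delta = sigma_g^2 / sigma_e^2``. The kinship is rescaled internally to
unit mean diagonal so that ``h2_SNP = sigma_g^2 / (sigma_g^2 + sigma_e^2)``
is the proportion of trait variance captured by the relatedness matrix.
Per-SNP tests are generalized-least-squares Wald t-tests reusing the null
variance components (the usual EMMAX/"population parameters previously
estimated" shortcut that makes genome scans linear-time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator

from .core import GenotypeMatrix
from .popstruct import Kinship, compute_grm


@dataclass
class NullModelFit:
    """Variance components and fixed effects of a fitted null mixed model."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    loglik: float
    h2_snp: float
    family: str
    trait: str = ""
    converged: bool = True
    _ctx: dict = field(default_factory=dict, repr=False)


def _check_design(X: np.ndarray, names=None):
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        names = names or [f"x{j}" for j in range(p)]
        aliased = []
        rank = 0
        for j in range(p):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                aliased.append(names[j])
            rank = r
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _eigen_kinship(K: np.ndarray):
    n = len(K)
    if np.trace(K) <= 0:
        raise ValueError("kinship matrix is not PSD even after jitter")
    K = K / (np.trace(K) / n)  # unit mean diagonal
    vals, vecs = np.linalg.eigh(K + 1e-8 * np.eye(n))
    if vals[0] < -1e-6:
        raise ValueError("kinship matrix is not PSD even after jitter")
    return np.clip(vals, 0.0, None), vecs


def _reml_neg_loglik(log_delta: float, S, ystar, Xstar):
    delta = np.exp(log_delta)
    n, p = Xstar.shape
    v = delta * S + 1.0
    w = 1.0 / v
    Xw = Xstar * w[:, None]
    XtVX = Xstar.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    rss = float(np.sum(r * r * w))
    sigma_e2 = rss / (n - p)
    _, ld_xvx = np.linalg.slogdet(XtVX)
    _, ld_xx = np.linalg.slogdet(Xstar.T @ Xstar)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma_e2) + 1.0)
                 + np.sum(np.log(v)) + ld_xvx - ld_xx)
    return -ll, beta, sigma_e2


def _reml_grad(log_delta: float, S, ystar, Xstar):
    """d REML-loglik / d log(delta) for the rotated model."""
    delta = np.exp(log_delta)
    n, p = Xstar.shape
    v = delta * S + 1.0
    w = 1.0 / v
    Xw = Xstar * w[:, None]
    XtVX = Xstar.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    rss = float(np.sum(r * r * w))
    d_rss = -float(np.sum(S * (r * w) ** 2))
    d_logdet_v = float(np.sum(S * w))
    Xsw2 = Xstar * (S * w * w)[:, None]
    d_logdet_x = float(np.trace(np.linalg.solve(XtVX, Xstar.T @ Xsw2))) * -1.0
    dl_ddelta = -0.5 * ((n - p) * d_rss / rss + d_logdet_v + d_logdet_x)
    return dl_ddelta * delta


def fit_lmm_null(y, X, K: Kinship | np.ndarray, trait: str = "") -> NullModelFit:
    """REML fit of the Gaussian null mixed model.

    Parameters: trait vector y, fixed-effect design X (must include the
    intercept), kinship K. Raises on rank-deficient X (naming the aliased
    columns) and on a kinship that is not PSD after jitter.
    """
    y = np.asarray(y, dtype=float).ravel()
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if n < 30:
        raise ValueError("mixed-model fit needs at least 30 samples")
    if X.shape[0] != n:
        raise ValueError("X and y lengths differ")
    _check_design(X, names)
    Kmat = K.K if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    if Kmat.shape != (n, n):
        raise ValueError("kinship dimension does not match samples")
    S, U = _eigen_kinship(Kmat)
    scale = float(np.std(y))
    if scale == 0:
        raise ValueError("trait has zero variance")
    ystar, Xstar = U.T @ (y / scale), U.T @ X

    # locate the REML optimum via the stationarity condition: a sign change
    # of the analytic gradient localizes log(delta) far below the noise
    # floor of the likelihood values themselves
    grid = np.linspace(-12.0, 12.0, 49)
    gvals = np.array([_reml_grad(ld, S, ystar, Xstar) for ld in grid])
    brackets = [(grid[i], grid[i + 1]) for i in range(len(grid) - 1)
                if gvals[i] > 0 >= gvals[i + 1]]
    candidates = [-12.0, 12.0]
    for a, b in brackets:
        candidates.append(brentq(_reml_grad, a, b, args=(S, ystar, Xstar),
                                 xtol=1e-12))
    best_ld, best = None, np.inf
    for ld in candidates:
        cand = _reml_neg_loglik(ld, S, ystar, Xstar)[0]
        if cand < best:
            best, best_ld = cand, ld
    neg_ll, beta, sigma_e2 = _reml_neg_loglik(best_ld, S, ystar, Xstar)
    delta = float(np.exp(best_ld))
    sigma_e2 *= scale ** 2
    sigma_g2 = delta * sigma_e2
    h2 = delta / (1.0 + delta)
    n_, p_ = Xstar.shape
    return NullModelFit(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, beta=beta * scale,
        loglik=-neg_ll - (n_ - p_) * np.log(scale),
        h2_snp=h2, family="gaussian", trait=trait,
        _ctx={"U": U, "S": S, "delta": delta, "ystar": ystar * scale,
              "Xstar": Xstar, "y": y, "X": X},
    )


def lmm_snp_tests(null: NullModelFit, dosages: np.ndarray) -> pd.DataFrame:
    """GLS Wald tests for each dosage column, reusing null variance components.

    Missing dosages (negative sentinel) are mean-imputed per SNP. Monomorphic
    columns yield NaN statistics with a skip reason.
    """
    ctx = null._ctx
    U, S, delta = ctx["U"], ctx["S"], ctx["delta"]
    ystar, Xstar = ctx["ystar"], ctx["Xstar"]
    n, p = Xstar.shape
    D = np.array(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    miss = D < 0
    if miss.any():
        mu = np.nanmean(np.where(miss, np.nan, D), axis=0)
        D = np.where(miss, mu[None, :], D)
    mono = D.std(axis=0) == 0

    w = 1.0 / np.sqrt(delta * S + 1.0)
    yw = ystar * w
    Xw = Xstar * w[:, None]
    Gw = (U.T @ D) * w[:, None]
    Q, _ = np.linalg.qr(Xw)
    y_perp = yw - Q @ (Q.T @ yw)
    G_perp = Gw - Q @ (Q.T @ Gw)

    gg = np.einsum("ij,ij->j", G_perp, G_perp)
    gy = G_perp.T @ y_perp
    yy = float(y_perp @ y_perp)
    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = yy - beta * gy
        se = np.sqrt(np.maximum(rss, 0.0) / df / gg)
        stat = beta / se
    pval = 2.0 * t_dist.sf(np.abs(stat), df)
    out = pd.DataFrame({"beta": beta, "se": se, "stat": stat, "p": pval,
                        "test": "lmm_wald"})
    out.loc[mono, ["beta", "se", "stat", "p"]] = np.nan
    out["skip"] = np.where(mono, "monomorphic", "")
    return out


def lmm_snp_test(null: NullModelFit, g) -> dict:
    """Single-SNP convenience wrapper around :func:`lmm_snp_tests`."""
    return lmm_snp_tests(null, np.asarray(g, dtype=float)).iloc[0].to_dict()


class LinearMixedGWAS(BaseEstimator):
    """Genome scan with a kinship-corrected linear mixed model.

    Parameters
    ----------
    maf_min, max_missing : per-SNP filters applied before testing.
    h2_screen : traits whose null-model h2_SNP falls at or below this value
        are flagged (``passes_screen_`` False); the scan still runs so the
        gate can be overridden downstream.

    Fitted attributes: ``null_`` (NullModelFit), ``results_`` (per-SNP
    table: chrom, pos, maf, beta, se, stat, p, test).
    """

    def __init__(self, maf_min: float = 0.05, max_missing: float = 0.10,
                 h2_screen: float = 0.10):
        self.maf_min = maf_min
        self.max_missing = max_missing
        self.h2_screen = h2_screen

    def fit(self, G: GenotypeMatrix, y, covariates=None, kinship=None,
            trait: str = ""):
        y, X, Gs, K = _align_inputs(G, y, covariates, kinship, self.maf_min)
        Gs = Gs.filtered(maf_min=self.maf_min, max_missing=self.max_missing)
        self.null_ = fit_lmm_null(y, X, K, trait=trait)
        self.passes_screen_ = bool(self.null_.h2_snp > self.h2_screen)
        res = lmm_snp_tests(self.null_, Gs.dosages)
        res.insert(0, "chrom", Gs.chrom.astype(str))
        res.insert(1, "pos", Gs.pos)
        res.insert(2, "maf", Gs.maf())
        self.results_ = res[res["skip"] == ""].drop(columns="skip").reset_index(drop=True)
        return self


def _align_inputs(G: GenotypeMatrix, y, covariates, kinship, grm_maf_min):
    """Subset genotypes/kinship to the samples carrying a trait value.

    ``y`` may be a Series indexed by genotype id (subset allowed) or an
    array aligned with ``G.sample_ids``. Covariates follow the same rule;
    categorical covariates are dummy-encoded (first level dropped).
    Returns (y array, design matrix with intercept, genotype subset, kinship
    subarray).
    """
    ids = list(G.sample_ids)
    if isinstance(y, pd.Series):
        common = [s for s in ids if s in y.index]
        if not common:
            raise ValueError("no overlap between trait index and sample ids")
        rows = [ids.index(s) for s in common]
        yv = y.loc[common].to_numpy(float)
    else:
        yv = np.asarray(y, dtype=float).ravel()
        if yv.size != len(ids):
            raise ValueError("array trait must align with sample_ids")
        rows = np.flatnonzero(~np.isnan(yv)).tolist()
        common = [ids[i] for i in rows]
        yv = yv[rows]
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    if covariates is not None:
        C = covariates if isinstance(covariates, pd.DataFrame) else pd.DataFrame(
            np.asarray(covariates), index=ids)
        C = C.loc[common]
        C = pd.get_dummies(C, drop_first=True, dtype=float)
        cols.append(C.to_numpy(float).T)
        names.extend(str(c) for c in C.columns)
    X = np.column_stack([c if c.ndim == 1 else c.T for c in cols])
    X = pd.DataFrame(X, columns=names)
    kin = kinship if kinship is not None else compute_grm(G, maf_min=grm_maf_min)
    Kmat = kin.K if isinstance(kin, Kinship) else np.asarray(kin, float)
    Ksub = Kmat[np.ix_(rows, rows)]
    Gsub = GenotypeMatrix(G.dosages[rows, :], G.chrom, G.pos, common,
                          None if G.subpop is None else G.subpop[rows])
    return yv, X, Gsub, Ksub
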