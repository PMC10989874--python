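"""Trait transformations toward normality and PCA-derived traits.

The transformation toolkit mirrors what a mixed-model GWAS of zero-inflated
proportion traits needs: removal of the structural zeros, an optional
elbow/outlier cleanup, then either a Box-Cox power transform (MLE lambda) or
a rank-based inverse-normal (RB-INV) map. Each transform is monotone, so the
Spearman correlation with the raw trait is 1 and ranks of evidence are
preserved. PCA over trait batches (callus, shoot, or both, across
timepoints) is centered but not rescaled, since all inputs already live on
the common proportion-of-plant-area scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

ZERO_TOL = 1e-12


def drop_zeros(x):
    """Strictly positive subset of x and the indices kept.

    Values within ZERO_TOL of zero count as structural zeros.
    """
    x = np.asarray(x, dtype=float)
    kept = np.flatnonzero(x > ZERO_TOL)
    if kept.size == 0:
        warnings.warn("all values are zero; nothing retained", stacklevel=2)
    return x[kept], kept


def dichotomize(x, tol: float = ZERO_TOL) -> np.ndarray:
    """Binary recoding: 0 for zero trait values, 1 for nonzero."""
    x = np.asarray(x, dtype=float)
    y = (x > tol).astype(int)
    if y.all() or not y.any():
        warnings.warn("dichotomized trait has no variation", stacklevel=2)
    return y


class BoxCoxTransformer(BaseEstimator, TransformerMixin):
    """Box-Cox power transform with maximum-likelihood lambda.

    ``fit`` maximizes the profile log-likelihood of lambda on strictly
    positive data; ``transform`` applies ``(x**lmbda - 1)/lmbda`` (log at
    lambda = 0). A fixed ``lmbda`` skips estimation.

    Attributes
    ----------
    lmbda_ : float
        Estimated (or fixed) power parameter.
    profile_ : (grid, log-likelihood) arrays over ``profile_range``.
    """

    def __init__(self, lmbda: float | None = None, profile_range=(-2.0, 2.0),
                 profile_points: int = 201):
        self.lmbda = lmbda
        self.profile_range = profile_range
        self.profile_points = profile_points

    @staticmethod
    def _check(x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size < 10:
            raise ValueError("Box-Cox needs at least 10 observations")
        if np.any(x <= 0):
            raise ValueError("Box-Cox requires strictly positive values")
        if np.ptp(x) == 0:
            raise ValueError("constant input: Box-Cox likelihood is degenerate")
        return x

    def fit(self, X, y=None):
        x = self._check(X)
        if self.lmbda is None:
            _, lam = stats.boxcox(x)
            self.lmbda_ = float(lam)
        else:
            self.lmbda_ = float(self.lmbda)
        grid = np.linspace(*self.profile_range, self.profile_points)
        ll = np.array([stats.boxcox_llf(g, x) for g in grid])
        self.profile_ = (grid, ll)
        return self

    def transform(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        if np.any(x <= 0):
            raise ValueError("Box-Cox requires strictly positive values")
        return special.boxcox(x, self.lmbda_)


def boxcox_mle(x):
    """Thin wrapper: fit + transform; returns (transformed, lmbda, profile)."""
    t = BoxCoxTransformer().fit(x)
    return t.transform(x), t.lmbda_, t.profile_


class RankInverseNormal(BaseEstimator, TransformerMixin):
    """Rank-based inverse-normal (RB-INV) transform with the Blom offset.

    ``z_i = Phi^{-1}((r_i - c) / (n - 2c + 1))`` with ``c = 3/8`` by default;
    ties share their mid-rank. The transform is defined by the sample's own
    ranks, so ``fit`` is stateless and ``fit_transform`` is the natural verb.
    """

    def __init__(self, c: float = 3.0 / 8.0):
        self.c = c

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        r = stats.rankdata(x, method="average")
        return stats.norm.ppf((r - self.c) / (x.size - 2 * self.c + 1))


def rank_inverse_normal(x, c: float = 3.0 / 8.0) -> np.ndarray:
    return RankInverseNormal(c=c).fit_transform(x)


def elbow_threshold(x, grid_points: int = 512):
    """Left-tail cutoff at the elbow of the frequency distribution.

    A Gaussian KDE (Silverman bandwidth) on a fixed grid estimates the
    frequency distribution. The main mode is the rightmost local maximum
    carrying at least 5% of the peak density; the cutoff is the grid point
    maximizing the finite-difference second derivative on the segment
    between the last density valley left of the main mode and the mode
    itself — the bend where the analyzable mass begins. A distribution with
    no valley left of its main mode (unimodal) has no dominant elbow: a
    warning is issued and None is returned (no removal). The same applies
    when the candidate cutoff falls below the 1st percentile of the data.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 50:
        raise ValueError("elbow estimation needs at least 50 observations")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_max = (dens[interior] > dens[interior - 1]) & \
             (dens[interior] >= dens[interior + 1])
    modes = interior[is_max & (dens[interior] >= 0.05 * dens.max())]
    if modes.size == 0:
        modes = np.array([int(np.argmax(dens))])
    main = int(modes[-1])
    is_min = (dens[interior] < dens[interior - 1]) & \
             (dens[interior] <= dens[interior + 1])
    valleys = interior[is_min]
    valleys = valleys[valleys < main]
    if valleys.size == 0:
        warnings.warn("no valley left of the main mode; no elbow removal",
                      stacklevel=2)
        return None
    seg_lo = int(valleys[-1])
    d2 = np.gradient(np.gradient(dens, grid), grid)
    cut_idx = seg_lo + int(np.argmax(d2[seg_lo:main + 1]))
    cutoff = float(grid[cut_idx])
    if cutoff <= np.percentile(x, 1):
        warnings.warn("elbow below 1st percentile; no removal", stacklevel=2)
        return None
    return cutoff


def normality_report(x) -> dict:
    """Shapiro-Wilk W/p plus Pearson r of sorted data vs matched normal quantiles."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("normality report needs at least 3 observations")
    w, p = stats.shapiro(x)
    n = x.size
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n, loc=x.mean(), scale=x.std())
    r = float(np.corrcoef(np.sort(x), q)[0, 1])
    return {"shapiro_w": float(w), "shapiro_p": float(p), "pearson_r": r}


class TraitPCA(BaseEstimator, TransformerMixin):
    """Centered, unscaled PCA over a batch of timepoint traits.

    Genotypes with any missing value in the batch are excluded, and
    genotypes that are zero for every trait in the batch (the spike of
    totally recalcitrant genotypes) are removed before the decomposition.
    PC1/PC2 scores are the derived analysis traits.

    Attributes
    ----------
    loadings_ : (n_traits, n_components) orthonormal columns.
    scores_ : (n_kept, n_components) genotype scores.
    variance_explained_ : fraction of total variance per component.
    included_ids_ : genotype ids entering the decomposition.
    n_all_zero_removed_ : size of the removed all-zero spike.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] < 2:
            raise ValueError("PCA batch needs at least 2 traits")
        complete = X.dropna()
        nz = ~(np.abs(complete.to_numpy(float)) <= ZERO_TOL).all(axis=1)
        self.n_all_zero_removed_ = int((~nz).sum())
        kept = complete.loc[nz]
        if len(kept) < 10:
            raise ValueError("fewer than 10 complete genotypes for PCA")
        pca = PCA(n_components=self.n_components)
        scores = pca.fit_transform(kept.to_numpy(float))
        # deterministic sign: largest-magnitude loading positive
        for j in range(pca.components_.shape[0]):
            i = np.argmax(np.abs(pca.components_[j]))
            if pca.components_[j, i] < 0:
                pca.components_[j] *= -1
                scores[:, j] *= -1
        self.loadings_ = pca.components_.T
        self.scores_ = scores
        self.variance_explained_ = pca.explained_variance_ratio_
        self.included_ids_ = list(kept.index)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.scores_.shape[1])]
        return pd.DataFrame(self.scores_, index=self.included_ids_, columns=cols)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform()


def trait_pca(X: pd.DataFrame, n_components: int = 2) -> TraitPCA:
    return TraitPCA(n_components=n_components).fit(X)


def transform_trait(x, method: str = "boxcox", drop_zero: bool = True,
                    elbow: bool = False, outlier_z: float | None = 4.0):
    """Per-trait preparation pipeline with an audit of removals.

    Steps (each optional): drop structural zeros -> elbow threshold ->
    transform (boxcox | rbinv | none) -> extreme-outlier removal at
    ``|z| > outlier_z`` on the transformed scale. Returns
    (values, kept original indices, audit dict); the audit records counts
    removed at each step and the transform parameters.
    """
    x = np.asarray(x, dtype=float).ravel()
    kept = np.flatnonzero(~np.isnan(x))
    audit = {"n_input": int(x.size), "n_missing": int(x.size - kept.size),
             "method": method}
    v = x[kept]
    if drop_zero:
        v2, sub = drop_zeros(v)
        audit["n_zero_removed"] = int(v.size - v2.size)
        kept, v = kept[sub], v2
    if elbow:
        cut = elbow_threshold(v)
        if cut is not None:
            sub = np.flatnonzero(v >= cut)
            audit["n_elbow_removed"] = int(v.size - sub.size)
            audit["elbow_cutoff"] = cut
            kept, v = kept[sub], v[sub]
        else:
            audit["n_elbow_removed"] = 0
    if method == "boxcox":
        t = BoxCoxTransformer().fit(v)
        v = t.transform(v)
        audit["lambda"] = t.lmbda_
    elif method == "rbinv":
        v = rank_inverse_normal(v)
    elif method != "none":
        raise ValueError(f"unknown transform method {method!r}")
    if outlier_z is not None and method != "rbinv" and v.size >= 10:
        z = (v - v.mean()) / v.std()
        sub = np.flatnonzero(np.abs(z) <= outlier_z)
        audit["n_outlier_removed"] = int(v.size - sub.size)
        kept, v = kept[sub], v[sub]
    if method == "rbinv":
        # re-rank after any removals so scores remain exact normal quantiles
        v = rank_inverse_normal(x[kept])
    audit["n_final"] = int(v.size)
    return v, kept, audit
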