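"""Genetic relatedness, structure covariates and LD-decay summaries.

The relatedness matrix is the centered genomic relationship matrix (GRM)
``K = Z Z' / m`` over SNPs passing a MAF filter, with ``Z`` the
column-centered dosage matrix — the same construction GEMMA uses for its
default ("-gk 1") relatedness matrix. Sample principal components for the
"P model" structure covariates are eigenvectors of the GRM scaled by the
square roots of their eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

from .core import GenotypeMatrix


@dataclass
class Kinship:
    """Symmetric sample x sample relatedness matrix with a method tag."""

    K: np.ndarray
    method: str
    sample_ids: list

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship not symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])


def compute_grm(G: GenotypeMatrix, maf_min: float = 0.01,
                standardized: bool = False) -> Kinship:
    """Centered (optionally standardized) GRM over SNPs with MAF >= maf_min.

    Missing dosages are mean-imputed per SNP before centering.
    """
    keep = (G.maf() >= maf_min) & ~G.is_monomorphic()
    m = int(keep.sum())
    if m == 0:
        raise ValueError("no SNPs remain after MAF filter; cannot build GRM")
    Z = G.imputed()[:, keep]
    Z = Z - Z.mean(axis=0)
    if standardized:
        sd = Z.std(axis=0)
        Z = Z / sd
    K = Z @ Z.T / m
    tag = "standardized" if standardized else "centered"
    return Kinship(K=K, method=tag, sample_ids=list(G.sample_ids))


class GenotypePCA(BaseEstimator):
    """Principal components of the SNP data for structure covariates (P model).

    PCs are eigenvectors of the GRM scaled by root-eigenvalues, with a
    deterministic sign convention (the largest-magnitude loading of each PC
    is positive).

    Parameters
    ----------
    n_components : int
        Number of PCs to return.
    maf_min : float
        MAF filter applied before building the GRM.
    """

    def __init__(self, n_components: int = 5, maf_min: float = 0.01):
        self.n_components = n_components
        self.maf_min = maf_min

    def fit(self, G: GenotypeMatrix, y=None):
        kin = compute_grm(G, maf_min=self.maf_min)
        vals, vecs = np.linalg.eigh(kin.K)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        rank = int((vals > 1e-9 * max(vals[0], 1.0)).sum())
        if self.n_components > rank:
            raise ValueError(
                f"requested {self.n_components} PCs but GRM rank is {rank}")
        vals = np.clip(vals[: self.n_components], 0.0, None)
        vecs = vecs[:, : self.n_components]
        for j in range(vecs.shape[1]):  # sign convention
            i = np.argmax(np.abs(vecs[:, j]))
            if vecs[i, j] < 0:
                vecs[:, j] = -vecs[:, j]
        self.eigenvalues_ = vals
        self.components_ = vecs * np.sqrt(vals)[None, :]
        self.kinship_ = kin
        return self

    def transform(self, G=None) -> np.ndarray:
        """Return the fitted sample PC scores (n_samples x n_components)."""
        return self.components_

    def fit_transform(self, G: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(G).transform()


def genotype_pca(G: GenotypeMatrix, k: int = 5, maf_min: float = 0.01) -> np.ndarray:
    """Top-k sample PCs of the SNP data (thin wrapper over GenotypePCA)."""
    return GenotypePCA(n_components=k, maf_min=maf_min).fit_transform(G)


def ld_decay(G: GenotypeMatrix, max_dist: int = 10_000, bin_width: int = 500):
    """Pairwise LD (r^2) against distance, binned, with a smoothing spline.

    r^2 is the squared Pearson correlation of (imputed) dosages for every
    intra-chromosomal SNP pair separated by at most ``max_dist`` bp. Returns
    a DataFrame of bins (empty bins omitted) and a cubic spline through the
    bin means (None when fewer than 4 non-empty bins).
    """
    D = G.imputed()
    D = D - D.mean(axis=0)
    sd = D.std(axis=0)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    chroms = G.chrom.astype(str)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        pos = G.pos[idx]
        for a, j in enumerate(idx):
            if sd[j] == 0:
                continue
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            nbr = idx[a + 1: hi]
            nbr = nbr[sd[nbr] > 0]
            if nbr.size == 0:
                continue
            r = (D[:, nbr].T @ D[:, j]) / (len(D) * sd[j] * sd[nbr])
            d = G.pos[nbr] - pos[a]
            b = np.minimum((d - 1) // bin_width, n_bins - 1)
            np.add.at(sums, b, r ** 2)
            np.add.at(counts, b, 1)
    rows = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        rows.append({
            "dist_lo": b * bin_width + 1,
            "dist_hi": (b + 1) * bin_width,
            "mean_r2": sums[b] / counts[b],
            "n_pairs": counts[b],
        })
    bins = pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "mean_r2", "n_pairs"])
    spline = None
    if len(bins) >= 4:
        mid = (bins["dist_lo"] + bins["dist_hi"]) / 2.0
        spline = CubicSpline(mid.to_numpy(), bins["mean_r2"].to_numpy())
    return bins, spline
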