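"""Set-based SKAT over staggered SNP windows with Monte-Carlo empirical
p-values.

Windows of 3 kb staggered by 1 kb tile each chromosome. For a window with
dosage matrix ``G_w`` and SNP weights ``w`` (Beta(1,25) density of the MAF
by default), the statistic is the weighted kernel quadratic form
``Q = r' G_w W^2 G_w' r`` in the null-model residuals ``r`` of the trait on
its covariates (including structure covariates). The parametric p-value
comes from the exact weighted-chi-square tail; because the trait need not be
transformed for this to be usable, an adaptive permutation scheme
(Freedman-Lane: residuals are permuted and re-projected, holding the
covariate fit fixed) supplies empirical p-values for windows the parametric
screen flags. Each window draws from its own RNG stream keyed by
(seed, chromosome, window start), so results are bit-identical regardless
of worker count or scheduling.
"""

from __future__ import annotations

import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator

from .core import GenotypeMatrix
from .quadform import quadform_tail


@dataclass
class SnpWindow:
    """Genomic window (1-based inclusive) with member SNP indices."""

    chrom: str
    start: int
    end: int
    snp_idx: np.ndarray


def make_windows(chrom, pos, width: int = 3000, step: int = 1000):
    """Staggered windows anchored at position 1, keeping only non-empty ones.

    Consecutive windows on a chromosome overlap by ``width - step``.
    """
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos)
    windows = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        k_lo = max(0, int(np.ceil((p.min() - width) / step)))
        k_hi = int((p.max() - 1) // step)
        for k in range(k_lo, k_hi + 1):
            start = 1 + k * step
            end = start + width - 1
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="right")
            if hi > lo:
                windows.append(SnpWindow(c, start, end, idx[lo:hi]))
    return windows


def beta_maf_weights(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """SKAT default per-SNP weights: Beta(a, b) density evaluated at the MAF."""
    return beta_dist.pdf(np.asarray(maf, dtype=float), a, b)


def skat_stat(resid, G_w, weights) -> float:
    """Q = r' G_w W^2 G_w' r (equivalently the squared weighted score norm)."""
    s = (np.asarray(G_w, float).T @ np.asarray(resid, float)) * np.asarray(weights, float)
    return float(s @ s)


def skat_pvalue(Q: float, G_w, weights, H, sigma2: float):
    """Parametric p for Q under the Gaussian null with hat matrix H.

    The null distribution is a positively weighted sum of chi2_1 with
    weights = nonzero eigenvalues of ``sigma2 * W G_w'(I-H)G_w W``.
    Returns (p, method tag) where the tag records a Liu fallback.
    """
    G_w = np.asarray(G_w, float)
    w = np.asarray(weights, float)
    M = G_w - H @ G_w
    B = (G_w.T @ M) * np.outer(w, w)
    lam = np.linalg.eigvalsh((B + B.T) / 2.0) * sigma2
    return quadform_tail(Q, np.clip(lam, 0.0, None))


def empirical_pvalue(Q_obs: float, M: np.ndarray, resid: np.ndarray,
                     rng: np.random.Generator, alpha: float,
                     b_stages=(1000, 10_000, 100_000)):
    """Adaptive permutation p-value for one window.

    ``M = W G_w'(I-H)`` maps a permuted residual vector straight to its
    weighted score, so each permutation costs one small matrix product.
    ``p = (b+1)/(B+1)``; B escalates through ``b_stages`` and stops early
    once the Clopper-Pearson 99% CI for p excludes ``alpha``. Returns
    (p_emp, B, converged).
    """
    n = resid.size
    b = 0
    B = 0
    for target in b_stages:
        extra = target - B
        if extra <= 0:
            continue
        # batched permutations, chunked to bound memory
        done = 0
        while done < extra:
            chunk = min(20_000, extra - done)
            perm = rng.random((chunk, n)).argsort(axis=1)
            Qs = np.einsum("ij,bj->bi", M, resid[perm])
            Qs = np.einsum("bi,bi->b", Qs, Qs)
            b += int(np.count_nonzero(Qs >= Q_obs))
            done += chunk
        B = target
        p = (b + 1) / (B + 1)
        # Clopper-Pearson 99% interval for the exceedance probability
        lo = beta_dist.ppf(0.005, b, B - b + 1) if b > 0 else 0.0
        hi = beta_dist.ppf(0.995, b + 1, B - b) if b < B else 1.0
        if lo > alpha or hi < alpha:
            return p, B, True
    return (b + 1) / (B + 1), B, False


def _window_seed(seed: int, chrom: str, start: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(chrom.encode()), int(start))))


class WindowSKAT(BaseEstimator):
    """SKAT genome scan over staggered windows with adaptive empirical p-values.

    Parameters
    ----------
    width, step : window geometry in bp (3 kb staggered by 1 kb).
    weights : "beta" for Beta(1,25) MAF weights, "flat" for unweighted.
    p_threshold : parametric-p gate below which a window earns an empirical
        p-value.
    b_stages : escalating permutation counts; the last entry is B_max.
    alpha : significance level the adaptive CI tests against; defaults to a
        Bonferroni level 0.05 / n_windows.
    n_workers : thread count for the empirical stage (results identical for
        any value).
    seed : base seed for the per-window RNG streams.

    Fitted attribute ``results_``: chrom, start, end, n_snps, Q, p_param,
    p_method, p_emp, B, converged.
    """

    def __init__(self, width: int = 3000, step: int = 1000,
                 weights: str = "beta", beta_params=(1.0, 25.0),
                 p_threshold: float = 1e-3, b_stages=(1000, 10_000, 100_000),
                 alpha: float | None = None, n_workers: int = 1, seed: int = 0):
        self.width = width
        self.step = step
        self.weights = weights
        self.beta_params = beta_params
        self.p_threshold = p_threshold
        self.b_stages = b_stages
        self.alpha = alpha
        self.n_workers = n_workers
        self.seed = seed

    def fit(self, G: GenotypeMatrix, y, covariates=None):
        """Scan all windows of G for association with the (untransformed) trait.

        ``covariates`` is an optional design of nuisance columns (diameter,
        phase dummies, structure PCs); an intercept is always included.
        """
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if n != G.n_samples:
            raise ValueError("trait length must match sample count")
        X = np.ones((n, 1))
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            X = np.column_stack([X, C])
        Qx, _ = np.linalg.qr(X)
        H = Qx @ Qx.T
        resid = y - H @ y
        sigma2 = float(resid @ resid) / (n - X.shape[1])

        D = G.imputed()
        maf = G.maf()
        if self.weights == "beta":
            wts = beta_maf_weights(maf, *self.beta_params)
        elif self.weights == "flat":
            wts = np.ones_like(maf)
        else:
            raise ValueError(f"unknown weight scheme {self.weights!r}")

        windows = make_windows(G.chrom, G.pos, self.width, self.step)
        self.windows_ = windows
        alpha = self.alpha if self.alpha is not None else (
            0.05 / max(len(windows), 1))

        rows = []
        gated = []
        for wd in windows:
            Gw = D[:, wd.snp_idx]
            w = wts[wd.snp_idx]
            Q = skat_stat(resid, Gw, w)
            p_param, tag = skat_pvalue(Q, Gw, w, H, sigma2)
            rows.append({"chrom": wd.chrom, "start": wd.start, "end": wd.end,
                         "n_snps": len(wd.snp_idx), "Q": Q, "p_param": p_param,
                         "p_method": tag, "p_emp": np.nan, "B": 0,
                         "converged": True})
            if p_param <= self.p_threshold:
                gated.append((len(rows) - 1, wd, Gw, w, Q))

        def run_one(job):
            i, wd, Gw, w, Q = job
            M = (Gw - H @ Gw).T * w[:, None]  # W G'(I-H)
            rng = _window_seed(self.seed, wd.chrom, wd.start)
            p_emp, B, conv = empirical_pvalue(Q, M, resid, rng, alpha,
                                              self.b_stages)
            return i, p_emp, B, conv

        if self.n_workers > 1 and gated:
            with ThreadPoolExecutor(max_workers=self.n_workers) as ex:
                done = list(ex.map(run_one, gated))
        else:
            done = [run_one(j) for j in gated]
        for i, p_emp, B, conv in done:
            rows[i].update({"p_emp": p_emp, "B": B, "converged": conv})

        self.results_ = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_snps", "Q", "p_param",
                           "p_method", "p_emp", "B", "converged"])
        return self
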