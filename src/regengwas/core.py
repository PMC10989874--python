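"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel for a missing dosage call.
MISSING = -1

#: Default class encoding for segmentation masks.
DEFAULT_CLASS_MAP = {0: "background", 1: "stem", 2: "callus", 3: "shoot"}


@dataclass
class GenotypeMatrix:
    """Sample x SNP dosage matrix with positional metadata.

    Dosages count copies of the alternate allele (0/1/2); missing calls carry
    the sentinel :data:`MISSING`. Positions are 1-based and strictly
    increasing within each chromosome.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_samples, n_snps)``.
    chrom
        Chromosome label per SNP.
    pos
        1-based coordinate per SNP.
    sample_ids
        Sample identifiers, length ``n_samples``.
    subpop
        Optional subpopulation label per sample (simulation ground truth).
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list
    subpop: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.ascontiguousarray(np.asarray(self.dosages, dtype=np.int8))
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)
        if self.subpop is not None:
            self.subpop = np.asarray(self.subpop)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if self.chrom.shape != (m,) or self.pos.shape != (m,):
            raise ValueError("chrom/pos must have one entry per SNP")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or the missing sentinel")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls."""
        d = self.dosages.astype(float)
        ok = d != MISSING
        n_ok = ok.sum(axis=0)
        if np.any(n_ok == 0):
            raise ValueError("SNP with no non-missing calls; frequency undefined")
        return np.where(ok, d, 0.0).sum(axis=0) / (2.0 * n_ok)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def is_monomorphic(self) -> np.ndarray:
        """Flag SNPs with no dosage variation among non-missing calls."""
        d = self.dosages
        out = np.empty(self.n_snps, dtype=bool)
        for j in range(self.n_snps):
            col = d[:, j]
            col = col[col != MISSING]
            out[j] = col.size == 0 or np.all(col == col[0])
        return out

    def imputed(self) -> np.ndarray:
        """Float dosage matrix with per-SNP mean imputation of missing calls."""
        d = self.dosages.astype(float)
        miss = d == MISSING
        if miss.any():
            col_mean = np.where(miss, np.nan, d)
            col_mean = np.nanmean(col_mean, axis=0)
            d = np.where(miss, col_mean[None, :], d)
        return d

    def select_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.chrom[idx], self.pos[idx],
            self.sample_ids, self.subpop,
        )

    def filtered(self, maf_min: float = 0.0, max_missing: float = 1.0) -> "GenotypeMatrix":
        """Subset to SNPs passing MAF and missingness filters (monomorphic always dropped)."""
        keep = (self.maf() >= maf_min) & (self.missing_rate() <= max_missing)
        keep &= ~self.is_monomorphic()
        return self.select_snps(np.where(keep)[0])
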