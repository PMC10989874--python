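"""Synthetic study generator: structured genotypes, zero-inflated regeneration
traits, segmentation masks and a toy gene annotation.

The generator emulates the features of a wild, strongly structured tree GWAS
population that matter to the analysis stages: several ancestral
subpopulations (Balding-Nichols allele-frequency divergence), rapid LD decay
(optional adjacent-SNP copying, off by default), zero-inflated right-skewed
proportion traits driven by a thresholded liability, covariates (stem
diameter, phenotyping phase) correlated with subpopulation so that structure
correction is genuinely exercised, and planted causal SNPs with known effect
sizes. Every output is fully determined by the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import GenotypeMatrix
from .popstruct import compute_grm
from .traits import SegmentationMask

#: Weekly timepoints phenotyped in the study design this generator mirrors.
TIMEPOINTS = (2, 3, 4, 5)

# Liability offsets per timepoint: callus rises steadily; shoots are nearly
# absent at week 2 and emerge later, giving the early-timepoint zero spike.
_CALLUS_OFFSETS = {2: -0.4, 3: 0.0, 4: 0.2, 5: 0.35}
_SHOOT_OFFSETS = {2: -1.3, 3: -0.5, 4: 0.0, 5: 0.25}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_samples, n_snps : int
        Population and marker panel size.
    n_subpops : int
        Number of ancestral subpopulations (the study population supports 6).
    fst : float
        Balding-Nichols divergence parameter in [0, 1).
    maf_range : tuple
        Uniform support of ancestral allele frequencies.
    causal_loci : tuple of (snp index, effect size b)
        Planted causal SNPs; effects act on standardized dosages.
    h2_poly : float
        Polygenic variance fraction of the (covariate-free) liability.
    zero_threshold : float
        Liability cut tau: samples with liability below tau are recalcitrant
        (trait value exactly 0). The standardized liability is ~N(0,1), so
        the expected zero fraction is Phi(tau).
    diameter_slope, phase_offsets : covariate effects on the liability.
    n_replicates : int
        Clonal replicates per genotype (independent residual noise).
    chrom_lengths : dict
        Chromosome name -> length in bp.
    ld_copy, ld_range_bp : optional LD by adjacent-SNP copying (default off):
        a sample's dosage is copied from the previous SNP with probability
        ``ld_copy * exp(-distance / ld_range_bp)``.
    """

    n_samples: int = 600
    n_snps: int = 5000
    n_subpops: int = 6
    fst: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    causal_loci: tuple = ()
    h2_poly: float = 0.3
    zero_threshold: float = -0.5
    diameter_slope: float = 0.3
    phase_offsets: tuple = (0.0, 0.15, -0.1, 0.05)
    n_replicates: int = 2
    chrom_lengths: dict = field(default_factory=lambda: {"Chr01": 2_000_000,
                                                         "Chr02": 2_000_000})
    ld_copy: float = 0.0
    ld_range_bp: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        c = sum(b * b for _, b in self.causal_loci)
        if self.h2_poly + c > 1.0 + 1e-12:
            raise ValueError("h2_poly + explained causal variance exceeds 1")
        if not (0.0 <= self.h2_poly < 1.0):
            raise ValueError("h2_poly must lie in [0, 1)")

    @property
    def causal_variance(self) -> float:
        return sum(b * b for _, b in self.causal_loci)


def _rng(cfg: SimulationConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed,) + key))


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw a structured dosage matrix under the Balding-Nichols model.

    Ancestral frequencies are Uniform over ``maf_range``; each subpopulation's
    frequency is Beta(p(1-fst)/fst, (1-p)(1-fst)/fst) around the ancestral p
    (degenerate at p when fst=0); dosages are Binomial(2, subpop frequency).
    """
    rng = _rng(cfg, 1)
    n, m, s = cfg.n_samples, cfg.n_snps, cfg.n_subpops
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    if cfg.fst > 0:
        ratio = (1.0 - cfg.fst) / cfg.fst
        p_sub = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(s, m))
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    else:
        p_sub = np.broadcast_to(p_anc, (s, m)).copy()
    subpop = np.arange(n) % s
    dosages = rng.binomial(2, p_sub[subpop, :]).astype(np.int8)

    # chromosome layout: SNPs spread over chromosomes proportional to length
    chroms, lengths = zip(*sorted(cfg.chrom_lengths.items()))
    lengths = np.asarray(lengths, dtype=float)
    counts = np.floor(m * lengths / lengths.sum()).astype(int)
    counts[0] += m - counts.sum()
    chrom_col, pos_col = [], []
    for c, L, k in zip(chroms, lengths, counts):
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, int(L) + 1), size=k, replace=False))
        chrom_col.extend([c] * k)
        pos_col.append(pos)
    pos_col = np.concatenate(pos_col)
    chrom_col = np.asarray(chrom_col, dtype=object)

    if cfg.ld_copy > 0:
        for j in range(1, m):
            if chrom_col[j] != chrom_col[j - 1]:
                continue
            d = pos_col[j] - pos_col[j - 1]
            pr = cfg.ld_copy * math.exp(-d / cfg.ld_range_bp)
            copy = rng.random(n) < pr
            dosages[copy, j] = dosages[copy, j - 1]

    return GenotypeMatrix(dosages=dosages, chrom=chrom_col, pos=pos_col,
                          sample_ids=[f"S{i:04d}" for i in range(n)],
                          subpop=subpop)


def simulate_covariates(G: GenotypeMatrix, cfg: SimulationConfig):
    """Stem diameter and phenotyping phase, mildly confounded with subpopulation.

    Returns (diameter, phase index array, liability contribution).
    """
    rng = _rng(cfg, 2)
    n = G.n_samples
    sub = G.subpop if G.subpop is not None else np.zeros(n, dtype=int)
    n_phase = len(cfg.phase_offsets)
    shift = 0.15 * (sub - np.mean(sub))
    diameter = np.exp(rng.normal(1.5 + shift, 0.25, size=n))
    phase = (sub + rng.integers(0, 2, size=n)) % n_phase
    diam_std = (diameter - diameter.mean()) / diameter.std()
    term = cfg.diameter_slope * diam_std + np.asarray(cfg.phase_offsets)[phase]
    return diameter, phase, term


def _polygenic(G: GenotypeMatrix, cfg: SimulationConfig, stream: int) -> np.ndarray:
    """Polygenic effect u ~ N(0, h2_poly * K) with K trace-normalized."""
    if cfg.h2_poly == 0:
        return np.zeros(G.n_samples)
    K = compute_grm(G, maf_min=0.0).K
    K = K / (np.trace(K) / len(K))
    L = np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))
    z = _rng(cfg, 3, stream).standard_normal(len(K))
    return math.sqrt(cfg.h2_poly) * (L @ z)


def _causal(G: GenotypeMatrix, cfg: SimulationConfig) -> np.ndarray:
    out = np.zeros(G.n_samples)
    D = None
    for j, b in cfg.causal_loci:
        if not (0 <= j < G.n_snps):
            raise IndexError(f"causal SNP index {j} out of range")
        if D is None:
            D = G.imputed()
        g = D[:, j]
        sd = g.std()
        if sd == 0:
            raise ValueError(f"causal SNP {j} is monomorphic")
        out += b * (g - g.mean()) / sd
    return out


def _squash(liab: np.ndarray, tau: float) -> np.ndarray:
    """0 below tau, else affine rescale of the exceedance into (0, 1]."""
    out = np.zeros_like(liab)
    pos = liab >= tau
    if pos.any():
        top = liab[pos].max() - tau
        if top <= 0:
            out[pos] = 1.0
        else:
            out[pos] = np.maximum((liab[pos] - tau) / top, 1e-9)
    return out


def simulate_trait_values(G: GenotypeMatrix, cfg: SimulationConfig,
                          timepoint_offset: float = 0.0, stream: int = 0):
    """Zero-inflated proportion trait for each sample x replicate.

    Liability per replicate: ``L = sum_j b_j g~_j + u + X beta_cov + offset
    + eps`` with Var(causal + u + eps) = 1, so the covariate-free liability is
    standard normal and the zero fraction converges to Phi(tau - offset).
    Observed values are 0 below tau, else a monotone affine squash into (0,1].

    Returns (values array (n_samples, n_replicates), info dict with the
    liability components and covariates).
    """
    var_eps = 1.0 - cfg.h2_poly - cfg.causal_variance
    if var_eps < -1e-12:
        raise ValueError("variance budget exceeded")
    var_eps = max(var_eps, 0.0)
    gcaus = _causal(G, cfg)
    u = _polygenic(G, cfg, stream)
    diameter, phase, cov_term = simulate_covariates(G, cfg)
    rng = _rng(cfg, 4, stream)
    eps = math.sqrt(var_eps) * rng.standard_normal((G.n_samples, cfg.n_replicates))
    liab = (gcaus + u + cov_term + timepoint_offset)[:, None] + eps
    vals = np.column_stack([_squash(liab[:, r], cfg.zero_threshold)
                            for r in range(cfg.n_replicates)])
    info = {"liability": liab, "causal": gcaus, "polygenic": u,
            "covariate_term": cov_term, "diameter": diameter, "phase": phase}
    return vals, info


def simulate_traits(G: GenotypeMatrix, cfg: SimulationConfig) -> pd.DataFrame:
    """Full replicate-level trait table across timepoints.

    Callus area carries the planted causal and polygenic signal; shoot area
    shares the covariates but has its own (independent) polygenic background,
    acting as a nuisance trait. Columns: genotype_id, replicate, timepoint,
    callus_area, shoot_area, diameter, phase.
    """
    rows = []
    shoot_cfg = cfg
    for t in TIMEPOINTS:
        callus, info = simulate_trait_values(G, cfg, _CALLUS_OFFSETS[t],
                                             stream=0)
        shoot, _ = simulate_trait_values(G, shoot_cfg, _SHOOT_OFFSETS[t],
                                         stream=100 + t)
        for r in range(cfg.n_replicates):
            rows.append(pd.DataFrame({
                "genotype_id": G.sample_ids,
                "replicate": r + 1,
                "timepoint": t,
                "callus_area": callus[:, r],
                "shoot_area": shoot[:, r],
                "diameter": info["diameter"],
                "phase": info["phase"],
            }))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["genotype_id", "timepoint", "replicate"],
                          ignore_index=True)


def simulate_masks(trait_rows, image_size=(64, 64), seed: int = 0):
    """Segmentation masks whose plant-pixel class proportions match requests.

    ``trait_rows`` is an iterable of (callus_area, shoot_area) pairs or
    mappings with those keys. The plant region is a contiguous disk; callus
    and shoot pixel counts are rounded to the nearest pixel.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    masks = []
    for row in trait_rows:
        if isinstance(row, (tuple, list)):
            c, s = float(row[0]), float(row[1])
        else:
            c, s = float(row["callus_area"]), float(row["shoot_area"])
        if not (0 <= c <= 1 and 0 <= s <= 1 and c + s <= 1 + 1e-12):
            raise ValueError("requested proportions must be in [0,1] and sum <= 1")
        cy = h / 2 + rng.integers(-2, 3)
        cx = w / 2 + rng.integers(-2, 3)
        r = 0.35 * min(h, w)
        plant = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        idx = np.flatnonzero(plant.ravel())
        n_plant = idx.size
        n_callus = int(round(c * n_plant))
        n_shoot = int(round(s * n_plant))
        labels = np.zeros(h * w, dtype=np.uint8)
        labels[idx] = 1  # stem
        labels[idx[:n_callus]] = 2
        labels[idx[n_callus:n_callus + n_shoot]] = 3
        masks.append(SegmentationMask(labels.reshape(h, w)))
    return masks


@dataclass
class ToyAnnotation:
    """Minimal gene annotation: list of (id, chrom, start, end, strand).

    Coordinates are 1-based closed intervals; the TSS is ``start`` on the
    plus strand and ``end`` on the minus strand.
    """

    genes: list

    def __post_init__(self):
        for gid, chrom, start, end, strand in self.genes:
            if start > end:
                raise ValueError(f"gene {gid}: start > end")
            if strand not in ("+", "-"):
                raise ValueError(f"gene {gid}: bad strand {strand!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genes,
                            columns=["gene_id", "chrom", "start", "end", "strand"])


def make_annotation(chrom_lengths: dict, n_genes_per_chrom: int = 20,
                    gene_length: tuple = (1000, 4000), seed: int = 0,
                    min_gap: int = 1000) -> ToyAnnotation:
    """Random non-overlapping toy genes with alternating-ish strands."""
    rng = np.random.default_rng(seed)
    genes = []
    i = 0
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        slot = L // n_genes_per_chrom
        for k in range(n_genes_per_chrom):
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            lo = k * slot + min_gap
            hi = (k + 1) * slot - glen - min_gap
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((f"gene{i:04d}", chrom, start, start + glen - 1, strand))
            i += 1
    return ToyAnnotation(genes=genes)
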