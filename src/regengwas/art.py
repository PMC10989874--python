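"""Augmented Rank Truncation (ART) combination of single-SNP p-values.

ART is a post hoc method: given the per-SNP p-values of a 1 kb window, the
product of the k smallest (k = ceil(L/2), the "upper half of top-ranking
SNPs") is augmented by a term based on the (k+1)-th order statistic so that
the combined statistic has an exact Gamma null distribution. Conditional on
``p_(k+1)``, the k smallest p-values are order statistics of k iid
U(0, p_(k+1)) draws, so ``T = sum_{i<=k} ln(p_(k+1)/p_(i)) ~ Gamma(k, 1)``
independently of ``p_(k+1)``; the augmentation
``A = -ln F_{Beta(k+1, L-k)}(p_(k+1)) ~ Exp(1)`` folds the location of the
truncation point back in, giving ``T + A ~ Gamma(k+1, 1)``. When k = L the
statistic reduces to Fisher's combination, and L = 1 returns the input
p-value unchanged.

Candidate windows come from an anchor scan over the association results: a
SNP with p below the anchor threshold that has at least ``min_neighbors``
other SNPs with p below the neighbor threshold within +/-500 bp seeds a
1 kb window centered on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special


def art_combine(p, k: int | None = None) -> float:
    """Combined p-value of the member p-values via Augmented Rank Truncation.

    ``k`` defaults to ceil(L/2). Inputs must lie in (0, 1].
    """
    p = np.sort(np.asarray(p, dtype=float).ravel())
    L = p.size
    if L == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if k is None:
        k = math.ceil(L / 2)
    if not (1 <= k <= L):
        raise ValueError("truncation k must lie in [1, L]")
    logp = np.log(p)
    if k == L:
        stat = -float(np.sum(logp))  # Fisher limit (identity at L = 1)
        return float(max(special.gammaincc(L, stat), np.nextafter(0, 1)))
    T = k * logp[k] - float(np.sum(logp[:k]))
    F = special.betainc(k + 1, L - k, p[k])
    A = -np.log(max(F, 1e-300))
    return float(max(special.gammaincc(k + 1, T + A), np.nextafter(0, 1)))


@dataclass
class ARTWindow:
    """1 kb candidate window around an anchor SNP, with its combined p."""

    chrom: str
    start: int
    end: int
    anchor_pos: int
    anchor_p: float
    member_pos: np.ndarray
    member_p: np.ndarray  # sorted ascending
    k: int = 0
    combined_p: float = field(default=np.nan)

    @property
    def L(self) -> int:
        return len(self.member_p)


def art_anchor_scan(assoc: pd.DataFrame, anchor_p: float = 1e-5,
                    neighbor_p: float = 1e-4, radius: int = 500,
                    min_neighbors: int = 5) -> list[ARTWindow]:
    """Find candidate 1 kb windows from a single-SNP association table.

    For every SNP with p < ``anchor_p``, count distinct other SNPs within
    +/- ``radius`` bp with p < ``neighbor_p``; when the count reaches
    ``min_neighbors`` emit the window centered on the anchor, whose members
    are all SNPs (anchor included) within the radius. Combined p-values are
    computed with k = ceil(L/2); ties in member p are broken by position
    (stable sort).
    """
    need = {"chrom", "pos", "p"}
    if not need <= set(assoc.columns):
        raise ValueError(f"association table must carry columns {sorted(need)}")
    out = []
    for chrom, sub in assoc.dropna(subset=["p"]).groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "p"], kind="stable")
        pos = sub["pos"].to_numpy(np.int64)
        pv = sub["p"].to_numpy(float)
        anchors = np.flatnonzero(pv < anchor_p)
        for a in anchors:
            lo = np.searchsorted(pos, pos[a] - radius, side="left")
            hi = np.searchsorted(pos, pos[a] + radius, side="right")
            nbr = np.arange(lo, hi)
            n_support = int(np.count_nonzero((pv[nbr] < neighbor_p)
                                             & (nbr != a)))
            if n_support < min_neighbors:
                continue
            order = np.argsort(pv[nbr], kind="stable")
            member_p = pv[nbr][order]
            member_pos = pos[nbr][order]
            k = math.ceil(len(nbr) / 2)
            out.append(ARTWindow(
                chrom=str(chrom), start=int(pos[a]) - radius,
                end=int(pos[a]) + radius - 1, anchor_pos=int(pos[a]),
                anchor_p=float(pv[a]), member_pos=member_pos,
                member_p=member_p, k=k,
                combined_p=art_combine(member_p, k)))
    return out


def art_windows_frame(windows: list[ARTWindow], threshold: float | None = None
                      ) -> pd.DataFrame:
    rows = [{"chrom": w.chrom, "window_start": w.start, "window_end": w.end,
             "anchor_pos": w.anchor_pos, "anchor_p": w.anchor_p, "L": w.L,
             "k": w.k, "p_combined": w.combined_p} for w in windows]
    df = pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                     "anchor_pos", "anchor_p", "L", "k",
                                     "p_combined"])
    if threshold is not None:
        df["pass_threshold"] = df["p_combined"] < threshold
    return df


def art_bonferroni_threshold(genome_bp: float, window_bp: float = 1000.0,
                             alpha: float = 0.05) -> float:
    """alpha divided by the approximate number of independent 1 kb windows."""
    if genome_bp <= 0 or window_bp <= 0:
        raise ValueError("genome and window sizes must be positive")
    return alpha / (genome_bp / window_bp)


def conservative_bonferroni(n_tests: int, alpha: float = 0.05) -> float:
    """alpha divided by the total number of tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def art_two_round_gmmat(score_assoc: pd.DataFrame, wald_callback,
                        threshold: float,
                        **scan_kwargs):
    """Two-round ART over logistic mixed-model results.

    Round 1 runs the anchor scan and ART on score-test p-values. For windows
    whose combined p passes ``threshold``, Wald p-values for the member SNPs
    are obtained through ``wald_callback(list of (chrom, pos))`` (a mapping
    {(chrom, pos): p}); round 2 recombines each passing window on the Wald
    p-values. Windows with a member lacking a Wald p are flagged incomplete.
    Returns (round-1 frame, round-2 frame).
    """
    round1 = art_anchor_scan(score_assoc, **scan_kwargs)
    r1 = art_windows_frame(round1, threshold)
    passing = [w for w in round1 if w.combined_p < threshold]
    keys = sorted({(w.chrom, int(pos)) for w in passing for pos in w.member_pos})
    wald_p = wald_callback(keys) if keys else {}
    rows = []
    for w in passing:
        ps = [wald_p.get((w.chrom, int(pos))) for pos in w.member_pos]
        complete = all(v is not None and np.isfinite(v) for v in ps)
        if complete:
            comb = art_combine(np.asarray(ps, float), w.k)
        else:
            comb = np.nan
        rows.append({"chrom": w.chrom, "window_start": w.start,
                     "window_end": w.end, "anchor_pos": w.anchor_pos,
                     "anchor_p": w.anchor_p, "L": w.L, "k": w.k,
                     "p_combined": comb, "complete": complete,
                     "pass_threshold": bool(complete and comb < threshold)})
    r2 = pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                     "anchor_pos", "anchor_p", "L", "k",
                                     "p_combined", "complete",
                                     "pass_threshold"])
    return r1, r2
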