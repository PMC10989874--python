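"""Multiple-testing tiers, QTL-peak deduplication and candidate-gene assignment.

Three significance tiers, from most to least conservative: Bonferroni over
every test ("conservative-Bonferroni"), Benjamini-Hochberg FDR at 0.10, and
the window-count Bonferroni used for ART. A tested locus is a QTL peak iff
no other locus within 30 kb carries a strictly smaller p-value (equal p:
leftmost wins). Each peak is assigned the gene that encompasses it or, if
intergenic, the nearest gene; distances are reported to the strand-aware
TSS, and a flag records whether the peak lies within 5 kb of the nearest
gene boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import ToyAnnotation


def bh_fdr(p, q: float = 0.10):
    """Benjamini-Hochberg step-up: (adjusted p, significance flags at q)."""
    p = np.asarray(p, dtype=float)
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def find_peaks(assoc: pd.DataFrame, radius: int = 30_000) -> pd.DataFrame:
    """Deduplicate signals: keep loci with no stronger p within +/- radius.

    "Stronger" means strictly smaller p; among equal-p neighbors the leftmost
    position survives. Output order (chrom, pos) is independent of input
    order.
    """
    need = {"chrom", "pos", "p"}
    if not need <= set(assoc.columns):
        raise ValueError(f"need columns {sorted(need)}")
    out = []
    for chrom, sub in assoc.dropna(subset=["p"]).groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "p"], kind="stable")
        pos = sub["pos"].to_numpy(np.int64)
        pv = sub["p"].to_numpy(float)
        keep = np.ones(len(sub), dtype=bool)
        for i in range(len(sub)):
            lo = np.searchsorted(pos, pos[i] - radius, side="left")
            hi = np.searchsorted(pos, pos[i] + radius, side="right")
            for j in range(lo, hi):
                if j == i:
                    continue
                if pv[j] < pv[i] or (pv[j] == pv[i] and pos[j] < pos[i]):
                    keep[i] = False
                    break
        out.append(sub.iloc[keep])
    if not out:
        return assoc.iloc[0:0]
    return pd.concat(out).sort_values(["chrom", "pos"], ignore_index=True)


@dataclass
class GeneAssignment:
    gene_id: str | None
    relation: str  # exonic | intragenic-nonexonic | 5' | 3' | unassigned
    tss_distance: int  # 0 when intragenic
    boundary_gap: int  # 0 when intragenic
    within_5kb: bool


def _tss(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end


def assign_gene(chrom: str, pos: int, annotation: ToyAnnotation,
                exons: dict | None = None,
                proximity_bp: int = 5000) -> GeneAssignment:
    """Assign the encompassing or nearest gene to a peak locus.

    Inside a gene body the relation is "exonic" when the locus overlaps an
    exon (genes without exon records are treated as single-exon models),
    else "intragenic-nonexonic"; TSS distance is reported as 0. Intergenic
    peaks take the gene with the smallest gap to its boundary (ties: nearer
    TSS, then leftmost gene), relation 5' or 3' by the gene's strand, and
    the distance to its TSS. ``within_5kb`` flags a boundary gap of at most
    ``proximity_bp``. An empty annotation yields an unassigned peak.
    """
    cand = [(gid, s, e, strand) for gid, c, s, e, strand in annotation.genes
            if c == chrom]
    if not cand:
        return GeneAssignment(None, "unassigned", -1, -1, False)
    inside = [g for g in cand if g[1] <= pos <= g[2]]
    if inside:
        gid, s, e, strand = min(inside, key=lambda g: (abs(pos - _tss(g[1], g[2], g[3])), g[1]))
        ex = (exons or {}).get(gid)
        if ex is None:
            relation = "exonic"
        else:
            relation = "exonic" if any(a <= pos <= b for a, b in ex) else \
                "intragenic-nonexonic"
        return GeneAssignment(gid, relation, 0, 0, True)

    def gap(g):
        return g[1] - pos if pos < g[1] else pos - g[2]

    gid, s, e, strand = min(
        cand, key=lambda g: (gap(g), abs(pos - _tss(g[1], g[2], g[3])), g[1]))
    tss = _tss(s, e, strand)
    if strand == "+":
        relation = "5'" if pos < s else "3'"
    else:
        relation = "5'" if pos > e else "3'"
    g = gap((gid, s, e, strand))
    return GeneAssignment(gid, relation, abs(pos - tss), g, g <= proximity_bp)


def call_peaks(assoc: pd.DataFrame, annotation: ToyAnnotation | None,
               thresholds: dict, method: str, radius: int = 30_000,
               assembled_chroms=None) -> pd.DataFrame:
    """Peaks + tiers + gene assignment for one association table.

    ``thresholds`` maps tier name -> p-value cutoff (e.g. conservative
    Bonferroni and the ART Bonferroni); the FDR tier is computed from the
    full p-value vector via BH at q=0.10. Loci on chromosomes outside
    ``assembled_chroms`` (when given) are excluded before any computation.
    """
    df = assoc.dropna(subset=["p"]).copy()
    if assembled_chroms is not None:
        df = df[df["chrom"].isin(set(assembled_chroms))]
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "p", "method", "tier",
                                     "gene_id", "relation", "tss_distance",
                                     "within_5kb"])
    _, fdr_sig = bh_fdr(df["p"].to_numpy(), q=thresholds.get("fdr_q", 0.10))
    df["fdr_significant"] = fdr_sig
    peaks = find_peaks(df, radius=radius)
    rows = []
    for _, r in peaks.iterrows():
        tier = None
        if "conservative_bonferroni" in thresholds and \
                r["p"] <= thresholds["conservative_bonferroni"]:
            tier = "conservative-Bonferroni"
        elif bool(r.get("fdr_significant", False)):
            tier = "FDR-0.10"
        elif "art_bonferroni" in thresholds and \
                r["p"] <= thresholds["art_bonferroni"]:
            tier = "ART-Bonferroni"
        if tier is None:
            continue
        if annotation is not None:
            ga = assign_gene(str(r["chrom"]), int(r["pos"]), annotation)
        else:
            ga = GeneAssignment(None, "unassigned", -1, -1, False)
        rows.append({"chrom": r["chrom"], "pos": int(r["pos"]),
                     "p": float(r["p"]), "method": method, "tier": tier,
                     "gene_id": ga.gene_id, "relation": ga.relation,
                     "tss_distance": ga.tss_distance,
                     "within_5kb": ga.within_5kb})
    return pd.DataFrame(rows, columns=["chrom", "pos", "p", "method", "tier",
                                       "gene_id", "relation", "tss_distance",
                                       "within_5kb"])


def summarize_tiers(peaks: pd.DataFrame) -> pd.DataFrame:
    """Counts of peaks per method x tier x within-5 kb flag."""
    cols = ["method", "tier", "within_5kb"]
    if peaks.empty:
        return pd.DataFrame(columns=cols + ["n"])
    out = (peaks.groupby(cols, sort=True).size().rename("n").reset_index())
    return out
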