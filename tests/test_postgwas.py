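"""FDR tiers, peak deduplication, gene assignment and tallies."""

import numpy as np
import pandas as pd
import pytest

from regengwas.postgwas import (assign_gene, bh_fdr, call_peaks, find_peaks,
                                summarize_tiers)
from regengwas.simulate import ToyAnnotation


class TestFDR:
    def test_step_up_oracle(self):
        adj, sig = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.10)
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert sig.tolist() == [True, True, True, False]

    def test_all_ones(self):
        adj, sig = bh_fdr([1.0, 1.0, 1.0])
        assert not sig.any()

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.05])
        assert adj[0] == pytest.approx(0.05)


def assoc(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "p"])


class TestFindPeaks:
    def test_stronger_neighbor_suppresses(self):
        res = find_peaks(assoc([("c1", 100_000, 1e-9), ("c1", 110_000, 1e-7)]))
        assert res["pos"].tolist() == [100_000]

    def test_distant_loci_both_peaks(self):
        res = find_peaks(assoc([("c1", 100_000, 1e-9), ("c1", 140_000, 1e-7)]))
        assert res["pos"].tolist() == [100_000, 140_000]

    def test_equal_p_leftmost_wins(self):
        res = find_peaks(assoc([("c1", 50_000, 1e-8), ("c1", 60_000, 1e-8)]))
        assert res["pos"].tolist() == [50_000]

    def test_order_invariance(self, rng):
        rows = [("c1", int(p), float(v)) for p, v in
                zip(rng.choice(np.arange(1, 500_000), 60, replace=False),
                    rng.uniform(1e-10, 1, 60))]
        a = find_peaks(assoc(rows))
        b = find_peaks(assoc(list(reversed(rows))))
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_chromosomes_independent(self):
        res = find_peaks(assoc([("c1", 10_000, 1e-9), ("c2", 15_000, 1e-7)]))
        assert len(res) == 2


ANN = ToyAnnotation(genes=[
    ("gA", "c1", 10_000, 12_000, "+"),
    ("gB", "c1", 40_000, 44_000, "-"),
    ("gC", "c1", 60_000, 62_000, "+"),
])


class TestAssignGene:
    def test_three_bp_upstream_plus_strand(self):
        ga = assign_gene("c1", 9_997, ANN)
        assert ga.gene_id == "gA"
        assert ga.relation == "5'"
        assert ga.tss_distance == 3
        assert ga.within_5kb

    def test_inside_gene_body_distance_zero(self):
        ga = assign_gene("c1", 11_000, ANN)
        assert ga.gene_id == "gA" and ga.relation == "exonic"
        assert ga.tss_distance == 0 and ga.within_5kb

    def test_exon_records_split_relation(self):
        exons = {"gA": [(10_000, 10_500)]}
        assert assign_gene("c1", 10_100, ANN, exons=exons).relation == "exonic"
        assert assign_gene("c1", 11_500, ANN, exons=exons).relation == \
            "intragenic-nonexonic"

    def test_minus_strand_tss_at_end(self):
        ga = assign_gene("c1", 44_500, ANN)  # 500 bp past gB's end
        assert ga.gene_id == "gB"
        assert ga.relation == "5'"  # upstream of a minus-strand gene
        assert ga.tss_distance == 500

    def test_equidistant_tie_breaks_to_nearer_tss(self):
        # midpoint between gB (ends 44,000, '-') and gC (starts 60,000, '+')
        ga = assign_gene("c1", 52_000, ANN)
        assert ga.gene_id == "gB"  # gB's TSS (44,000) is nearer than 60,000
        assert not ga.within_5kb

    def test_empty_annotation_unassigned(self):
        ga = assign_gene("c1", 1, ToyAnnotation(genes=[]))
        assert ga.gene_id is None and ga.relation == "unassigned"


class TestTiersAndSummary:
    def test_tier_assignment_and_monotonicity(self):
        df = assoc([("c1", 10_000, 1e-12), ("c1", 100_000, 1e-4),
                    ("c1", 200_000, 0.4)])
        peaks = call_peaks(df, ANN, {"conservative_bonferroni": 1e-8,
                                     "fdr_q": 0.10}, method="m")
        tiers = dict(zip(peaks["pos"], peaks["tier"]))
        assert tiers[10_000] == "conservative-Bonferroni"
        assert tiers[100_000] == "FDR-0.10"
        assert 200_000 not in tiers
        # every conservative peak also meets the FDR criterion
        adj, sig = bh_fdr(df["p"].to_numpy())
        assert sig[0]

    def test_summary_counts_fixture(self):
        peaks = pd.DataFrame({
            "method": ["m1", "m1", "m2"],
            "tier": ["conservative-Bonferroni", "FDR-0.10", "FDR-0.10"],
            "within_5kb": [True, False, True],
            "chrom": ["c1"] * 3, "pos": [1, 2, 3], "p": [1e-9] * 3,
        })
        out = summarize_tiers(peaks)
        assert out["n"].sum() == 3
        row = out[(out["method"] == "m1") & (out["tier"] == "FDR-0.10")]
        assert row["n"].iloc[0] == 1

    def test_unassembled_contigs_excluded(self):
        df = assoc([("c1", 10_000, 1e-12), ("scaffold_7", 5_000, 1e-13)])
        peaks = call_peaks(df, ANN, {"conservative_bonferroni": 1e-8,
                                     "fdr_q": 0.10}, method="m",
                           assembled_chroms={"c1"})
        assert peaks["chrom"].tolist() == ["c1"]

    def test_empty_input_all_zero(self):
        out = summarize_tiers(pd.DataFrame())
        assert len(out) == 0
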