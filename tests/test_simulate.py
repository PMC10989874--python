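"""Synthetic-study generator: determinism, divergence, zero inflation, masks."""

import numpy as np
import pytest
from scipy.stats import norm

from regengwas.core import GenotypeMatrix
from regengwas.simulate import (SimulationConfig, make_annotation,
                                simulate_genotypes, simulate_masks,
                                simulate_trait_values, simulate_traits)
from regengwas.traits import mask_class_proportions


def hudson_fst(G):
    """Textbook Hudson estimator (ratio of averages) for two subpopulations."""
    d = G.dosages.astype(float)
    sub = G.subpop
    p1 = d[sub == 0].mean(axis=0) / 2
    p2 = d[sub == 1].mean(axis=0) / 2
    n1, n2 = (sub == 0).sum(), (sub == 1).sum()
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


class TestGenotypes:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_samples=4, n_snps=3, seed=7)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.pos, b.pos)

    @pytest.mark.parametrize("fst", [0.0, 0.1])
    def test_hudson_fst_recovers_divergence(self, fst):
        cfg = SimulationConfig(n_samples=400, n_snps=5000, n_subpops=2,
                               fst=fst, h2_poly=0.0, seed=1)
        G = simulate_genotypes(cfg)
        assert abs(hudson_fst(G) - fst) < 0.03

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fst=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(fst=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(n_subpops=0)
        with pytest.raises(ValueError):
            SimulationConfig(h2_poly=0.9, causal_loci=((0, 0.5),))

    def test_realized_maf_within_range(self, small_structured):
        _, G = small_structured
        maf = G.maf()
        # Balding-Nichols spreads subpop frequencies around the ancestral
        # draw; allow sampling slack around the configured support
        assert (maf <= 0.5).all()
        assert np.quantile(maf, 0.9) > 0.05
        assert G.is_monomorphic().dtype == bool

    def test_positions_strictly_increasing_per_chrom(self, small_structured):
        _, G = small_structured
        for c in np.unique(G.chrom.astype(str)):
            p = G.pos[G.chrom.astype(str) == c]
            assert (np.diff(p) > 0).all()


class TestTraitsSim:
    def test_zero_fraction_matches_liability_cut(self):
        cfg = SimulationConfig(n_samples=2000, n_snps=200, n_subpops=1,
                               fst=0.0, h2_poly=0.2, zero_threshold=0.0,
                               diameter_slope=0.0,
                               phase_offsets=(0.0, 0.0, 0.0, 0.0), seed=3)
        G = simulate_genotypes(cfg)
        vals, _ = simulate_trait_values(G, cfg)
        frac = (vals == 0).mean()
        n = vals.size
        ci = 4 * np.sqrt(0.25 / n)
        assert abs(frac - norm.cdf(0.0)) < ci

    def test_very_low_threshold_gives_no_zeros(self):
        cfg = SimulationConfig(n_samples=200, n_snps=100, zero_threshold=-30.0,
                               seed=5)
        G = simulate_genotypes(cfg)
        vals, _ = simulate_trait_values(G, cfg)
        assert (vals > 0).all() and (vals <= 1).all()

    def test_null_trait_uncorrelated_with_snps(self):
        cfg = SimulationConfig(n_samples=400, n_snps=150, n_subpops=1, fst=0.0,
                               h2_poly=0.0, zero_threshold=-30.0,
                               diameter_slope=0.0,
                               phase_offsets=(0.0, 0.0, 0.0, 0.0), seed=9)
        G = simulate_genotypes(cfg)
        vals, _ = simulate_trait_values(G, cfg)
        y = vals.mean(axis=1)
        D = G.imputed()
        D = (D - D.mean(0)) / np.where(D.std(0) == 0, 1, D.std(0))
        r = np.abs(D.T @ ((y - y.mean()) / (y.std() * len(y))))
        # null correlations are ~N(0, 1/n); the bulk must sit inside 3/sqrt(n)
        assert np.quantile(r, 0.95) < 3.0 / np.sqrt(len(y))

    def test_causal_index_out_of_range(self):
        cfg = SimulationConfig(n_samples=50, n_snps=20,
                               causal_loci=((99, 0.3),), seed=1)
        G = simulate_genotypes(cfg)
        with pytest.raises(IndexError):
            simulate_trait_values(G, cfg)

    def test_full_table_shape_and_determinism(self):
        cfg = SimulationConfig(n_samples=40, n_snps=60, seed=11)
        G = simulate_genotypes(cfg)
        t1 = simulate_traits(G, cfg)
        t2 = simulate_traits(G, cfg)
        assert t1.equals(t2)
        assert set(t1["timepoint"]) == {2, 3, 4, 5}
        assert len(t1) == 40 * 4 * cfg.n_replicates
        ca, sa = t1["callus_area"], t1["shoot_area"]
        assert ((ca >= 0) & (ca <= 1)).all() and ((sa >= 0) & (sa <= 1)).all()
        # shoots are rarer than callus at the earliest timepoint
        wk2 = t1[t1["timepoint"] == 2]
        assert (wk2["shoot_area"] == 0).mean() > (wk2["callus_area"] == 0).mean()


class TestMasks:
    def test_requested_proportions_recovered(self):
        masks = simulate_masks([(0.1, 0.3), (0.25, 0.0)], image_size=(64, 64),
                               seed=1)
        for m, (c, s) in zip(masks, [(0.1, 0.3), (0.25, 0.0)]):
            got_c, got_s = mask_class_proportions(m)
            n_plant = int((m.labels > 0).sum())
            assert abs(got_c - c) <= 1.0 / n_plant
            assert abs(got_s - s) <= 1.0 / n_plant

    def test_zero_request_gives_stem_only(self):
        (m,) = simulate_masks([(0.0, 0.0)], seed=2)
        assert set(np.unique(m.labels)) <= {0, 1}

    def test_plant_region_contiguous(self):
        from scipy import ndimage

        (m,) = simulate_masks([(0.2, 0.2)], seed=3)
        _, n_components = ndimage.label(m.labels > 0)
        assert n_components == 1

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            simulate_masks([(0.7, 0.5)], seed=0)


class TestAnnotation:
    def test_toy_annotation_valid_intervals(self):
        ann = make_annotation({"Chr01": 100_000, "Chr02": 50_000},
                              n_genes_per_chrom=8, seed=4)
        for gid, chrom, start, end, strand in ann.genes:
            assert 1 <= start <= end
            assert strand in "+-"
        ids = [g[0] for g in ann.genes]
        assert len(ids) == len(set(ids))
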