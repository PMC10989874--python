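"""Windowed SKAT: windows, kernel statistic, parametric and empirical p."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest

from regengwas import quadform
from regengwas.quadform import quadform_tail
from regengwas.simulate import SimulationConfig, simulate_genotypes
from regengwas.skat import (WindowSKAT, beta_maf_weights, empirical_pvalue,
                            make_windows, skat_pvalue, skat_stat)


class TestWindows:
    def test_staggered_membership(self):
        wins = make_windows(["c"] * 3, [500, 1500, 3500], width=3000, step=1000)
        lookup = {(w.start, w.end): list(w.snp_idx) for w in wins}
        assert lookup[(1, 3000)] == [0, 1]
        assert lookup[(1001, 4000)] == [1, 2]
        for w in wins:
            assert all(w.start <= p <= w.end for p in
                       np.array([500, 1500, 3500])[w.snp_idx])

    def test_step_equals_width_is_disjoint_tiling(self):
        wins = make_windows(["c"] * 4, [10, 1010, 2010, 2990], width=1000,
                            step=1000)
        spans = [(w.start, w.end) for w in wins]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 > e1

    def test_no_snps_empty(self):
        assert make_windows([], []) == []

    def test_overlap_invariant(self):
        wins = make_windows(["c"] * 6, [100, 900, 1700, 2500, 3300, 4100])
        per_start = {w.start: w for w in wins}
        starts = sorted(per_start)
        for a, b in zip(starts, starts[1:]):
            assert b - a == 1000


class TestStatistic:
    def test_matches_dense_bruteforce(self, rng):
        r = rng.standard_normal(20)
        Gw = rng.binomial(2, 0.3, (20, 5)).astype(float)
        w = rng.uniform(0.5, 2.0, 5)
        Q = skat_stat(r, Gw, w)
        Kmat = Gw @ np.diag(w ** 2) @ Gw.T
        assert abs(Q - r @ Kmat @ r) < 1e-10

    def test_single_snp_window_is_squared_weighted_score(self, rng):
        r = rng.standard_normal(30)
        g = rng.binomial(2, 0.4, (30, 1)).astype(float)
        Q = skat_stat(r, g, [1.7])
        assert Q == pytest.approx((1.7 * float(g[:, 0] @ r)) ** 2)

    def test_orthogonal_residuals_give_zero(self):
        r = np.array([1.0, -1.0, 0.0, 0.0])
        g = np.array([[1.0], [1.0], [2.0], [0.0]])
        assert skat_stat(r, g, [1.0]) == 0.0

    def test_beta_weights_favor_rare(self):
        w = beta_maf_weights([0.01, 0.25, 0.5])
        assert w[0] > w[1] > w[2]


class TestParametricP:
    def test_single_eigenvalue_closed_form(self):
        p, tag = quadform_tail(7.0, [2.5])
        assert p == pytest.approx(chi2.sf(7.0 / 2.5, 1), abs=1e-12)

    def test_null_uniformity(self):
        n = 300
        H = np.full((n, n), 1.0 / n)
        ps = []
        for i in range(400):
            r = np.random.default_rng(i).standard_normal(n)
            Gw = np.random.default_rng(10_000 + i).binomial(
                2, 0.3, (n, 5)).astype(float)
            resid = r - H @ r
            s2 = resid @ resid / (n - 1)
            Q = skat_stat(resid, Gw, np.ones(5))
            p, _ = skat_pvalue(Q, Gw, np.ones(5), H, s2)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_liu_fallback_flagged(self, monkeypatch):
        def boom(q, lam):
            raise ArithmeticError("forced")

        monkeypatch.setattr(quadform, "_imhof_tail", boom)
        p, tag = quadform.quadform_tail(8.0, [3.0, 1.0, 0.5])
        assert tag == "liu"
        assert 0 < p < 1

    def test_residualization_invariance(self, rng):
        # adding any covariate-spanned component to y leaves Q unchanged
        n = 100
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        Qx, _ = np.linalg.qr(X)
        H = Qx @ Qx.T
        y = rng.standard_normal(n)
        Gw = rng.binomial(2, 0.3, (n, 4)).astype(float)
        w = np.ones(4)
        q1 = skat_stat(y - H @ y, Gw, w)
        y2 = y + X @ np.array([3.0, -1.2])
        q2 = skat_stat(y2 - H @ y2, Gw, w)
        assert q1 == pytest.approx(q2, rel=1e-10)


class TestEmpiricalP:
    def test_no_exceedance_formula(self, rng):
        n = 50
        M = rng.standard_normal((3, n))
        resid = rng.standard_normal(n)
        p, B, conv = empirical_pvalue(1e12, M, resid,
                                      np.random.default_rng(0), alpha=0.5,
                                      b_stages=(999,))
        assert p == pytest.approx(1.0 / 1000.0)
        assert B == 999

    def test_grid_values_and_uniformity(self):
        cfg = SimulationConfig(n_samples=150, n_snps=240, n_subpops=1,
                               fst=0.0, seed=5,
                               chrom_lengths={"Chr01": 120_000})
        G = simulate_genotypes(cfg)
        y = np.random.default_rng(3).standard_normal(150)
        sk = WindowSKAT(p_threshold=1.0, b_stages=(199,), alpha=1e-12, seed=1)
        sk.fit(G, y)
        pe = sk.results_["p_emp"].dropna().to_numpy()
        assert len(pe) == len(sk.results_)
        grid = pe * 200.0
        assert np.allclose(grid, np.round(grid))
        assert kstest(pe, "uniform").pvalue > 0.01

    def test_worker_count_does_not_change_results(self):
        cfg = SimulationConfig(n_samples=100, n_snps=120, n_subpops=1,
                               fst=0.0, seed=8,
                               chrom_lengths={"Chr01": 60_000})
        G = simulate_genotypes(cfg)
        y = np.random.default_rng(4).standard_normal(100)
        kw = dict(p_threshold=1.0, b_stages=(499,), alpha=1e-12, seed=3)
        r1 = WindowSKAT(n_workers=1, **kw).fit(G, y).results_
        r8 = WindowSKAT(n_workers=8, **kw).fit(G, y).results_
        assert r1.equals(r8)

    def test_empirical_tracks_parametric_for_gaussian_trait(self):
        cfg = SimulationConfig(n_samples=200, n_snps=200, n_subpops=1,
                               fst=0.0, seed=13,
                               chrom_lengths={"Chr01": 100_000})
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(7)
        # plant a modest window signal so p_param ~ 1e-2..1e-4
        y = rng.standard_normal(200) + 0.35 * G.imputed()[:, 50]
        sk = WindowSKAT(p_threshold=0.05, b_stages=(100_000,), alpha=1e-12,
                        seed=2, weights="flat")
        sk.fit(G, y)
        hit = sk.results_.dropna(subset=["p_emp"])
        hit = hit[hit["p_param"] > 1e-5]
        assert len(hit) > 0
        ratios = hit["p_emp"] / hit["p_param"]
        assert ((ratios > 0.5) & (ratios < 2.0)).all()
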