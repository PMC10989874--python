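"""Trait transformations: Box-Cox, RB-INV, elbow removal, PCA traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regengwas.prep import (BoxCoxTransformer, RankInverseNormal, TraitPCA,
                            dichotomize, drop_zeros, elbow_threshold,
                            normality_report, rank_inverse_normal,
                            transform_trait)


class TestDropZerosDichotomize:
    def test_drop_zeros(self):
        sub, kept = drop_zeros([0.0, 0.1, 0.3, 0.0])
        assert sub.tolist() == [0.1, 0.3]
        assert kept.tolist() == [1, 2]

    def test_all_zero_warns_empty(self):
        with pytest.warns(UserWarning):
            sub, kept = drop_zeros([0.0, 0.0])
        assert sub.size == 0

    def test_no_zeros_identity(self):
        sub, kept = drop_zeros([0.5, 0.1])
        assert sub.tolist() == [0.5, 0.1]

    def test_dichotomize(self):
        assert dichotomize([0.0, 0.2, 0.0]).tolist() == [0, 1, 0]
        assert dichotomize([0.0, 1e-13, 0.2]).tolist() == [0, 0, 1]
        with pytest.warns(UserWarning):
            dichotomize([0.1, 0.2])


class TestBoxCox:
    def test_mle_matches_grid_search_oracle(self, rng):
        x = rng.normal(10, 1, 500)
        t = BoxCoxTransformer().fit(x)
        grid = np.linspace(-2, 2, 2001)
        ll = [stats.boxcox_llf(g, x) for g in grid]
        lam_grid = grid[int(np.argmax(ll))]
        assert abs(t.lmbda_ - lam_grid) < 0.01
        assert abs(t.lmbda_ - 1.0) < 0.5

    def test_lognormal_gives_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(0, 1, 500))
        t = BoxCoxTransformer().fit(x)
        assert abs(t.lmbda_) < 0.2

    def test_fixed_lambda_one_is_shift(self, rng):
        x = rng.uniform(1, 5, 20)
        t = BoxCoxTransformer(lmbda=1.0).fit(x)
        assert np.allclose(t.transform(x), x - 1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            BoxCoxTransformer().fit([1.0] * 20)
        with pytest.raises(ValueError):
            BoxCoxTransformer().fit([1.0, -2.0] * 10)
        with pytest.raises(ValueError):
            BoxCoxTransformer().fit([1.0, 2.0])

    def test_monotone_hence_rank_preserving(self, rng):
        x = rng.gamma(2, 1, 200) + 0.1
        z = BoxCoxTransformer().fit_transform(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)


class TestRankInverseNormal:
    def test_three_point_normal_quantile_oracle(self):
        # z_i = Phi^-1((r_i - 3/8) / (n + 1/4))
        z = rank_inverse_normal([5.0, 1.0, 9.0])
        expect = stats.norm.ppf((np.array([2, 1, 3]) - 0.375) / 3.25)
        assert np.allclose(z, expect)
        assert z[1] == pytest.approx(-0.8694, abs=1e-3)

    def test_antisymmetric_for_symmetric_input(self):
        z = rank_inverse_normal([-3.0, -1.0, 0.0, 1.0, 3.0])
        assert np.allclose(z, -z[::-1])

    def test_ties_share_midrank(self):
        z = rank_inverse_normal([1.0, 1.0, 2.0])
        assert z[0] == z[1]

    def test_output_normal_by_shapiro(self, rng):
        x = rng.exponential(1, 200)
        z = RankInverseNormal().fit_transform(x)
        assert stats.shapiro(z).pvalue > 0.01
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)


class TestElbow:
    def test_mixture_cutoff_between_modes(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 800), rng.normal(1, 0.1, 200)])
        cut = elbow_threshold(x)
        assert 0.2 < cut < 0.8

    def test_unimodal_has_no_elbow(self, rng):
        with pytest.warns(UserWarning):
            assert elbow_threshold(rng.normal(0, 1, 500)) is None

    def test_translation_equivariance(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 800), rng.normal(1, 0.1, 200)])
        assert elbow_threshold(x + 3.7) == pytest.approx(
            elbow_threshold(x) + 3.7, abs=1e-6)

    def test_needs_enough_data(self):
        with pytest.raises(ValueError):
            elbow_threshold([1.0] * 10)


class TestNormalityReport:
    def test_perfect_normal_quantiles(self):
        x = stats.norm.ppf((np.arange(1, 201) - 0.5) / 200)
        rep = normality_report(x)
        assert rep["pearson_r"] > 0.999

    def test_transform_improves_fit(self, rng):
        x = rng.standard_cauchy(300)
        raw = normality_report(x)
        inv = normality_report(rank_inverse_normal(x))
        assert inv["pearson_r"] > raw["pearson_r"]

    def test_too_small(self):
        with pytest.raises(ValueError):
            normality_report([1.0, 2.0])


class TestTraitPCA:
    def test_perfectly_correlated_traits(self, rng):
        a = rng.uniform(0, 1, 50)
        X = pd.DataFrame({"t1": a, "t2": 2 * a}, index=[f"g{i}" for i in range(50)])
        pca = TraitPCA(n_components=1).fit(X)
        assert pca.variance_explained_[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (80, 4)))
        pca = TraitPCA(n_components=2).fit(X)
        eye = pca.loadings_.T @ pca.loadings_
        assert np.allclose(eye, np.eye(2), atol=1e-8)

    def test_rising_batch_shares_pc1_sign(self, rng):
        # all timepoint traits increase together -> PC1 loadings one-signed,
        # checked against a direct eigendecomposition oracle
        base = rng.uniform(0, 1, 200)
        X = pd.DataFrame({f"wk{t}": np.clip(base * (0.5 + 0.15 * t)
                                            + rng.normal(0, 0.02, 200), 0, 1)
                          for t in range(4)})
        pca = TraitPCA(n_components=2).fit(X)
        signs = np.sign(pca.loadings_[:, 0])
        assert np.all(signs == signs[0])
        C = np.cov((X - X.mean()).to_numpy().T)
        w, v = np.linalg.eigh(C)
        lead = v[:, np.argmax(w)]
        cos = abs(lead @ pca.loadings_[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_genotypes_removed_before_decomposition(self, rng):
        X = pd.DataFrame(rng.uniform(0.1, 1, (30, 3)))
        X.iloc[:5] = 0.0
        pca = TraitPCA().fit(X)
        assert pca.n_all_zero_removed_ == 5
        assert len(pca.included_ids_) == 25

    def test_requires_two_traits_and_enough_rows(self, rng):
        with pytest.raises(ValueError):
            TraitPCA().fit(pd.DataFrame({"a": rng.uniform(0, 1, 30)}))
        with pytest.raises(ValueError):
            TraitPCA().fit(pd.DataFrame(rng.uniform(0.2, 1, (5, 3))))


class TestTransformTrait:
    def test_audit_counts_sum(self, rng):
        x = np.concatenate([np.zeros(30), rng.gamma(2, 0.1, 170),
                            [np.nan] * 5])
        vals, kept, audit = transform_trait(x, method="boxcox")
        removed = (audit["n_missing"] + audit["n_zero_removed"]
                   + audit.get("n_elbow_removed", 0)
                   + audit.get("n_outlier_removed", 0))
        assert audit["n_input"] - removed == audit["n_final"] == vals.size
        assert kept.size == vals.size
        assert (x[kept] > 0).all()

    def test_rbinv_path_yields_exact_quantiles(self, rng):
        x = np.concatenate([np.zeros(20), rng.gamma(2, 0.1, 180)])
        vals, kept, audit = transform_trait(x, method="rbinv")
        expect = rank_inverse_normal(x[kept])
        assert np.allclose(vals, expect)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            transform_trait(np.ones(20), method="sqrt")
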