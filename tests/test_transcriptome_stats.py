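"""Normalization, moderated testing, clustering and qPCR computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pomewall.synthetic_data import ExpressionScenario, gen_expression
from pomewall.transcriptome_stats import (
    ExpressionMatrix,
    fold_change,
    hierarchical_cluster,
    lowess_normalize,
    moderated_ttest,
    quantile_normalize,
    relative_expression,
    select_differential,
    trigamma_inverse,
)


class TestLowess:
    def test_equal_channels_give_zero_ratios(self):
        x = np.linspace(100, 10000, 200)
        m, a = lowess_normalize(x, x)
        assert np.allclose(m, 0.0)

    def test_planted_smooth_bias_removed(self, rng):
        a_true = rng.uniform(6, 14, 2000)
        bias = 0.5 * np.sin(a_true)
        green = 2.0 ** (a_true - bias / 2)
        red = 2.0 ** (a_true + bias / 2)
        m, _ = lowess_normalize(red, green, frac=0.2)
        assert np.max(np.abs(m)) < 0.05

    def test_dye_swap_negates(self, rng):
        a_true = rng.uniform(6, 14, 500)
        bias = 0.3 * np.sin(a_true / 2)
        red = 2.0 ** (a_true + bias)
        green = 2.0**a_true
        m_fwd, _ = lowess_normalize(red, green)
        m_rev, _ = lowess_normalize(green, red)
        assert np.allclose(m_fwd, -m_rev, atol=1e-8)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            lowess_normalize(np.array([1.0, 0.0]), np.array([1.0, 2.0]))


class TestBackgroundSubtraction:
    def test_subtraction_and_floor(self):
        from pomewall.transcriptome_stats import subtract_background

        out = subtract_background(np.array([100.0, 10.0]), np.array([40.0, 30.0]))
        assert out.tolist() == [60.0, 0.5]

    def test_shape_mismatch_rejected(self):
        from pomewall.transcriptome_stats import subtract_background

        with pytest.raises(ValueError):
            subtract_background(np.ones(3), np.ones(4))


class TestQuantileNormalize:
    def test_hand_example(self):
        df = pd.DataFrame({"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [1.5, 3.5, 5.5]
        assert out["b"].tolist() == [1.5, 3.5, 5.5]

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_idempotent_and_distributions_identical(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)
        sorted_cols = np.sort(once.to_numpy(), axis=0)
        for j in range(1, 6):
            assert np.array_equal(sorted_cols[:, 0], sorted_cols[:, j])

    def test_rank_order_preserved(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = quantile_normalize(df)
        for c in df.columns:
            assert np.array_equal(
                np.argsort(df[c].to_numpy(), kind="mergesort"),
                np.argsort(out[c].to_numpy(), kind="mergesort"),
            )

    def test_ties_share_average(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan]}))


class TestModeratedTtest:
    def _null_matrix(self, rng, n_genes=2000, n=4):
        cols = [f"g1_{i}" for i in range(n)] + [f"g2_{i}" for i in range(n)]
        return (
            pd.DataFrame(rng.normal(8, 1, size=(n_genes, 2 * n)), columns=cols),
            cols[:n],
            cols[n:],
        )

    def test_d0_zero_equals_ordinary_t(self, rng):
        df, g1, g2 = self._null_matrix(rng, n_genes=100)
        res = moderated_ttest(df, g1, g2, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(df[g1], df[g2], axis=1)
        assert np.allclose(res.t, t_ref, atol=1e-10)
        assert np.allclose(res.p, p_ref, atol=1e-10)

    def test_d0_infinite_uses_common_variance(self, rng):
        df, g1, g2 = self._null_matrix(rng, n_genes=100)
        res = moderated_ttest(df, g1, g2, prior_df=np.inf)
        assert len(np.unique(np.round(res.s_post, 12))) == 1

    def test_posterior_variance_between_gene_and_prior(self, rng):
        df, g1, g2 = self._null_matrix(rng, n_genes=500)
        res = moderated_ttest(df, g1, g2)
        lo = np.minimum(res.s_g**2, res.prior_s**2) - 1e-12
        hi = np.maximum(res.s_g**2, res.prior_s**2) + 1e-12
        assert ((res.s_post**2 >= lo) & (res.s_post**2 <= hi)).all()
        assert res.prior_df >= 0

    def test_null_type_one_error_rate(self, rng):
        """Rejection rate at alpha=0.01 is 0.01 +/- 0.003 on 10,000 nulls."""
        df, g1, g2 = self._null_matrix(rng, n_genes=10_000)
        res = moderated_ttest(df, g1, g2)
        rate = float((res.p < 0.01).mean())
        assert abs(rate - 0.01) < 0.003

    def test_null_pvalues_uniform(self, rng):
        df, g1, g2 = self._null_matrix(rng, n_genes=10_000)
        res = moderated_ttest(df, g1, g2)
        ks = stats.kstest(res.p, "uniform")
        assert ks.pvalue > 0.01

    def test_prior_recovery_on_scaled_chisq_variances(self, rng):
        """d0 estimator recovers the generating prior on simulated variances."""
        d0_true, s0_true, d_g = 8.0, 1.3, 6
        n_genes = 20_000
        prior_var = s0_true**2 * d0_true / rng.chisquare(d0_true, n_genes)
        cols = [f"g1_{i}" for i in range(4)] + [f"g2_{i}" for i in range(4)]
        x = rng.normal(0, np.sqrt(prior_var)[:, None], size=(n_genes, 8))
        res = moderated_ttest(pd.DataFrame(x, columns=cols), cols[:4], cols[4:])
        assert res.prior_df == pytest.approx(d0_true, rel=0.15)
        assert res.prior_s == pytest.approx(s0_true, rel=0.05)

    def test_too_few_samples_rejected(self, rng):
        df, g1, g2 = self._null_matrix(rng, n_genes=10)
        with pytest.raises(ValueError):
            moderated_ttest(df, g1[:1], g2)

    def test_trigamma_inverse_is_inverse(self):
        from scipy.special import polygamma

        for x in (0.1, 1.0, 4.0, 50.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


class TestSelectDifferential:
    def test_power_on_planted_effects(self, rng):
        """50 planted 4-sd shifts among 1000 genes: nearly all recovered."""
        n = 4
        cols = [f"g1_{i}" for i in range(n)] + [f"g2_{i}" for i in range(n)]
        x = rng.normal(0, 1, size=(1000, 2 * n))
        x[:50, :n] += 4.0
        df = pd.DataFrame(x, columns=cols, index=[f"gene{i}" for i in range(1000)])
        res = moderated_ttest(df, cols[:n], cols[n:])
        sel = select_differential(res, alpha=0.01)
        planted = {f"gene{i}" for i in range(50)}
        assert len(planted & set(sel["up"])) >= 45

    def test_trivial_selections(self, rng):
        n = 4
        cols = [f"g1_{i}" for i in range(n)] + [f"g2_{i}" for i in range(n)]
        df = pd.DataFrame(rng.normal(size=(20, 2 * n)), columns=cols)
        res = moderated_ttest(df, cols[:n], cols[n:])
        assert len(select_differential(res, alpha=1.0)["all"]) == 20
        res.p = np.full(20, 0.5)
        assert len(select_differential(res, alpha=0.01)["all"]) == 0


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self):
        x = np.vstack([[1.0, 2.0, 3.0, 4.0]] * 2)
        out = hierarchical_cluster(x)
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        x = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        out = hierarchical_cluster(x)
        assert out["linkage"][0, 2] == pytest.approx(2.0)

    def test_two_template_recovery_ari_one(self, rng):
        t1 = np.sin(np.linspace(0, 3, 10))
        t2 = np.cos(np.linspace(0, 3, 10))
        truth = np.array([0] * 10 + [1] * 10)
        x = np.vstack([t1 + rng.normal(0, 0.05, 10) for _ in range(10)]
                      + [t2 + rng.normal(0, 0.05, 10) for _ in range(10)])
        out = hierarchical_cluster(x, k=2)
        assert adjusted_rand_score(truth, out["labels"]) == 1.0

    def test_scale_shift_invariance(self, rng):
        x = rng.normal(size=(8, 12))
        base = hierarchical_cluster(x, k=3)
        scaled = hierarchical_cluster(3.5 * x + 10.0, k=3)
        assert np.allclose(base["linkage"], scaled["linkage"])
        assert np.array_equal(base["labels"], scaled["labels"])

    def test_zero_variance_profile_named(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(x)


class TestQpcr:
    def test_target_equal_to_reference_mean(self):
        rec = relative_expression(20.0, (19.0, 20.0, 21.0))
        assert rec.delta_ct == 0.0
        assert rec.relative_expression == 1.0

    def test_hand_calculation(self):
        rec = relative_expression(23.0, (20.0, 20.0, 20.0))
        assert rec.delta_ct == 3.0
        assert rec.relative_expression == pytest.approx(0.125)

    def test_fold_change(self):
        assert fold_change(2.0, 5.0) == pytest.approx(8.0)

    def test_out_of_range_ct_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(50.0, (20.0, 20.0, 20.0))


class TestExpressionMatrix:
    def test_vocabularies_closed(self):
        values = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        samples = pd.DataFrame(
            {"sample": ["s1"], "stage": ["3M"], "genotype": ["H074"], "plot": ["PH"]}
        )
        with pytest.raises(ValueError, match="stage"):
            ExpressionMatrix(values=values, samples=samples)

    def test_tsv_roundtrip(self, tmp_path):
        matrix, _ = gen_expression(ExpressionScenario(n_genes=20, seed=3))
        matrix.to_tsv(tmp_path / "e.tsv", tmp_path / "s.tsv")
        back = ExpressionMatrix.from_tsv(tmp_path / "e.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.values, matrix.values, check_names=False)
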