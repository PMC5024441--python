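"""PCA, pooling, Pearson p-values and correlation networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from pomewall.integration import (
    DEFAULT_POOLS,
    build_network,
    correlate_biochem_transcript,
    pca,
    pearson_with_p,
    pool_genotypes,
)
from pomewall.synthetic_data import (
    BiochemScenario,
    ExpressionScenario,
    gen_biochem,
    gen_expression,
)


class TestPca:
    def test_collinear_points_explained_by_pc1(self):
        t = np.linspace(0, 1, 10)
        x = np.column_stack([t, 2 * t])
        res = pca(x)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_agrees_with_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(30, 6))
        res = pca(x)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(6):
            v = res.loadings.to_numpy()[:, j]
            w = evecs[:, j]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8
        total = evals.sum()
        assert np.allclose(res.explained_variance_ratio, evals[:6] / total, atol=1e-10)

    def test_reconstruction_at_full_rank(self, rng):
        x = rng.normal(size=(12, 5))
        res = pca(x)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + x.mean(axis=0)
        assert np.abs(recon - x).max() < 1e-8

    def test_isotropic_cloud_near_equal_variances(self, rng):
        x = rng.normal(size=(5000, 4))
        res = pca(x)
        assert np.ptp(res.explained_variance_ratio) < 0.03

    def test_stage_groups_separate_on_pc1(self, rng):
        """Two-group ion shift: PCA separates early vs mature fingerprints."""
        early = rng.normal([10, 1, 1, 5], 0.3, size=(9, 4))
        late = rng.normal([2, 8, 7, 5], 0.3, size=(9, 4))
        x = np.vstack([early, late])
        res = pca(x)
        labels = [0] * 9 + [1] * 9
        s = silhouette_score(res.scores.to_numpy()[:, :1], labels)
        assert s > 0.5

    def test_zero_variance_column_with_scale_rejected(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            pca(x, scale=True)


class TestPooling:
    def _matrix(self, rng, n_genes=5):
        scen = ExpressionScenario(n_genes=n_genes, seed=11, residual_sd=0.3)
        return gen_expression(scen)[0]

    def test_default_scheme_gives_15_columns(self, rng):
        em = self._matrix(rng)
        pooled = pool_genotypes(em.values, em.samples)
        assert pooled.shape[1] == 15
        assert set(pooled.columns.get_level_values("pool")) == set(DEFAULT_POOLS)

    def test_identical_profiles_pool_to_themselves(self):
        em = gen_expression(ExpressionScenario(n_genes=4, seed=0, residual_sd=0.0))[0]
        pooled = pool_genotypes(em.values, em.samples)
        col = em.values.iloc[:, 0]
        for c in pooled.columns:
            stage_cols = em.samples.loc[em.samples["stage"] == c[0], "sample"]
            expected = em.values[stage_cols].mean(axis=1)
            assert np.allclose(pooled[c], expected)

    def test_mean_over_members(self, rng):
        em = self._matrix(rng)
        pooled = pool_genotypes(em.values, em.samples)
        meta = em.samples.set_index("sample")
        sel = meta.index[(meta["stage"] == "H") & meta["genotype"].isin(DEFAULT_POOLS["Pool1"])]
        assert np.allclose(pooled[("H", "Pool1")], em.values[sel].mean(axis=1))

    def test_unknown_genotype_rejected(self, rng):
        em = self._matrix(rng)
        with pytest.raises(ValueError, match="unknown genotypes"):
            pool_genotypes(em.values, em.samples, {"P": ("NOPE",)})


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, x)
        assert r == 1.0 and p == 0.0 and n == 10

    def test_closed_form_r07_n16(self):
        """r=0.7 at n=16 gives t~3.67, p~0.0026 — inside the p<0.01 gate."""
        r = 0.7
        n = 16
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n - 2)
        assert t == pytest.approx(3.67, abs=0.01)
        assert p == pytest.approx(0.0026, abs=0.0002)
        # the implementation matches the closed form on data with that r
        x = np.arange(16.0)
        rng = np.random.default_rng(5)
        for _ in range(50):
            y = 0.7 * (x - x.mean()) / x.std() + rng.normal(0, 0.7, 16)
            r_i, p_i, _ = pearson_with_p(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert r_i == pytest.approx(r_ref, abs=1e-12)
            assert p_i == pytest.approx(p_ref, rel=1e-9)

    def test_null_pvalues_uniform(self, rng):
        ps = []
        x = rng.normal(size=20)
        for _ in range(2000):
            ps.append(pearson_with_p(x, rng.permutation(x))[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestNetwork:
    def test_near_identical_profiles_form_complete_graph(self, rng):
        base = rng.normal(size=20)
        profiles = pd.DataFrame(
            [base + rng.normal(0, 1e-6, 20) for _ in range(5)],
            index=[f"g{i}" for i in range(5)],
        )
        net = build_network(profiles)
        assert net.graph.number_of_edges() == 10
        assert len(net.components()[0]) == 5

    def test_impossible_threshold_empty(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(4, 10)))
        net = build_network(profiles, r_min=1.01)
        assert net.graph.number_of_edges() == 0

    def test_planted_module_recovered(self, rng):
        """10 correlated genes among 100: module found, few false edges.

        Profiles span the full design's 80 sample points (5 stages x 8
        genotypes x 2 plots), where r > 0.7 is far beyond null
        fluctuation, so spurious edges are rare.
        """
        n_pts = 80
        driver = rng.normal(size=n_pts)
        module = [driver + rng.normal(0, 0.3, n_pts) for _ in range(10)]
        noise = [rng.normal(size=n_pts) for _ in range(90)]
        profiles = pd.DataFrame(
            module + noise, index=[f"g{i}" for i in range(100)]
        )
        net = build_network(profiles, r_min=0.7, p_max=0.01)
        module_names = {f"g{i}" for i in range(10)}
        comps = net.components()
        big = max(comps, key=lambda c: len(c & module_names))
        assert len(big & module_names) >= 9
        false_edges = [
            e for e in net.edges
            if e.node1 not in module_names or e.node2 not in module_names
        ]
        assert len(false_edges) <= 2

    def test_absolute_mode_admits_negative_edges(self):
        x = np.arange(8.0)
        profiles = pd.DataFrame([x, -x + 0.01 * x**2], index=["up", "down"])
        assert build_network(profiles, signed_mode="positive").graph.number_of_edges() == 0
        assert build_network(profiles, signed_mode="absolute").graph.number_of_edges() == 1

    def test_symmetric_in_input_order(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(6, 12)), index=list("abcdef"))
        net1 = build_network(profiles, r_min=0.2, p_max=0.5)
        net2 = build_network(profiles.iloc[::-1], r_min=0.2, p_max=0.5)
        e1 = {frozenset((e.node1, e.node2)) for e in net1.edges}
        e2 = {frozenset((e.node1, e.node2)) for e in net2.edges}
        assert e1 == e2


class TestBiochemTranscript:
    def _pooled(self, seed=0, n_genes=40, effect=2.0):
        em, labels = gen_expression(
            ExpressionScenario(n_genes=n_genes, seed=seed, effect=effect,
                               frac_cluster_a=0.25, frac_cluster_b=0.25,
                               residual_sd=0.3)
        )
        pooled = pool_genotypes(em.values, em.samples)
        return pooled, labels

    def test_gene_equal_to_analyte_profile(self):
        _, reps = gen_biochem(BiochemScenario(seed=1))
        pooled = pd.DataFrame([reps.loc["Gal"].to_numpy()], index=["mimic"],
                              columns=reps.columns.set_names(["stage", "pool"]))
        out = correlate_biochem_transcript(reps, pooled)
        gal = out[(out["gene"] == "mimic") & (out["variable"] == "Gal")].iloc[0]
        assert gal["r"] == pytest.approx(1.0)
        assert gal["significant"]

    def test_axis_mismatch_rejected(self):
        _, reps = gen_biochem(BiochemScenario(seed=1))
        pooled, _ = self._pooled()
        with pytest.raises(ValueError, match="mismatch|stage"):
            correlate_biochem_transcript(reps.iloc[:, :-1], pooled)

    def test_cluster_a_positive_with_declining_gal(self):
        """Early-expressed genes track declining galactose positively."""
        pooled, labels = self._pooled(seed=4)
        _, reps = gen_biochem(BiochemScenario(seed=4))
        out = correlate_biochem_transcript(reps, pooled)
        a_genes = labels.index[labels == "A"]
        sub = out[(out["gene"].isin(a_genes)) & (out["variable"] == "Gal")]
        assert (sub["r"] > 0.7).mean() > 0.9
        assert sub["significant"].mean() > 0.9

    def test_null_gene_flag_rate(self, rng):
        """Independent genes flag at roughly the nominal 1% rate."""
        _, reps = gen_biochem(BiochemScenario(seed=9))
        n_null = 2000
        null = pd.DataFrame(
            rng.normal(size=(n_null, reps.shape[1])),
            index=[f"n{i}" for i in range(n_null)],
            columns=reps.columns.set_names(["stage", "pool"]),
        )
        out = correlate_biochem_transcript(reps, null)
        rate = out["significant"].mean()
        assert abs(rate - 0.01) < 0.008
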