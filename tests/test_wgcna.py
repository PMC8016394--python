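"""Similarity, adjacency, TOM, clustering, eigengene, and trait-correlation checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from coexpnet import (
    SynthConfig,
    WGCNA,
    adjacency,
    build_trait_matrix,
    cluster_genes,
    cut_modules,
    gene_significance,
    generate_expression,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    similarity,
    soft_threshold_scan,
    tom,
)
from coexpnet.wgcna import GREY


def brute_force_tom(A: np.ndarray) -> np.ndarray:
    """Independent triple-loop evaluation of the topological overlap formula."""
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return T


class TestSimilarity:
    def test_identical_and_anticorrelated_genes(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]],
                            index=["a", "b", "c"])
        S = similarity(expr)
        assert S.loc["a", "b"] == pytest.approx(1.0)
        assert S.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(S), 1.0)

    def test_hand_computed_three_gene_example(self):
        g1, g2, g3 = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0], [3.0, 2.0, 1.0]
        S = similarity(pd.DataFrame([g1, g2, g3], index=["g1", "g2", "g3"]))
        assert S.loc["g1", "g3"] == pytest.approx(-1.0)
        assert S.loc["g1", "g2"] == pytest.approx(pearsonr(g1, g2).statistic)

    def test_zero_variance_gene_named(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            similarity(expr)


class TestAdjacency:
    def test_forced_arithmetic(self):
        S = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        assert adjacency(S, beta=3, mode="unsigned").iloc[0, 1] == pytest.approx(0.125)
        assert adjacency(S, beta=3, mode="signed").iloc[0, 1] == pytest.approx(0.421875)

    def test_mode_contrast_at_perfect_anticorrelation(self):
        S = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
        assert adjacency(S, beta=2, mode="unsigned").iloc[0, 1] == pytest.approx(1.0)
        assert adjacency(S, beta=2, mode="signed").iloc[0, 1] == pytest.approx(0.0)
        assert adjacency(S, beta=5, mode="signed").iloc[0, 0] == 1.0

    def test_monotone_in_beta(self, rng):
        S = pd.DataFrame(np.clip(rng.uniform(0, 0.99, (6, 6)), 0, None))
        S = (S + S.T) / 2
        np.fill_diagonal(S.values, 1.0)
        for mode in ("signed", "unsigned"):
            A2 = adjacency(S, beta=2, mode=mode).to_numpy()
            A5 = adjacency(S, beta=5, mode=mode).to_numpy()
            off = ~np.eye(6, dtype=bool)
            assert (A5[off] <= A2[off] + 1e-15).all()


class TestTOM:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom(pd.DataFrame(A)).to_numpy()
            assert np.abs(T - brute_force_tom(A)).max() < 1e-12

    def test_complete_graph_gives_unit_overlap(self):
        A = pd.DataFrame(np.ones((5, 5)))
        assert np.allclose(tom(A).to_numpy(), 1.0)

    def test_empty_network_gives_zero_overlap(self):
        A = pd.DataFrame(np.eye(4))
        T = tom(A).to_numpy()
        assert np.allclose(T[~np.eye(4, dtype=bool)], 0.0)
        assert np.allclose(np.diag(T), 1.0)


class TestSoftThresholdScan:
    def test_scan_on_synthetic_data(self, synthetic_cohort):
        expr, _, _ = synthetic_cohort
        table = soft_threshold_scan(expr, betas=range(1, 9))
        assert ((table["r2"] >= 0) & (table["r2"] <= 1)).all()
        assert (np.diff(table["mean_k"]) < 0).all()
        if table["recommended"].any():
            assert table.loc[table["recommended"], "beta"].iloc[0] <= 6

    def test_scan_deterministic(self, synthetic_cohort):
        expr, _, _ = synthetic_cohort
        pd.testing.assert_frame_equal(soft_threshold_scan(expr), soft_threshold_scan(expr))


class TestClustering:
    def test_two_genes_single_merge(self):
        T = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=["a", "b"], columns=["a", "b"])
        Z = cluster_genes(T)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.3)

    def test_merge_heights_monotone(self, two_block_expr):
        expr, _ = two_block_expr
        Z = cluster_genes(tom(adjacency(similarity(expr))))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_planted_blocks_merge_within_before_between(self):
        n = 8
        T = np.full((n, n), 0.05)
        T[:4, :4] = 0.9
        T[4:, 4:] = 0.9
        np.fill_diagonal(T, 1.0)
        Z = cluster_genes(pd.DataFrame(T))
        # the first n-2 merges join members of the same block
        flat = fcluster(Z, 2, criterion="maxclust")
        assert len(set(flat[:4])) == 1 and len(set(flat[4:])) == 1


class TestCutModules:
    def test_degenerate_cut_gives_singletons(self, two_block_expr):
        expr, _ = two_block_expr
        Z = cluster_genes(tom(adjacency(similarity(expr))))
        first_merge = Z[:, 2].min()
        out = cut_modules(Z, min_module_size=1, cut_height=first_merge / 2,
                          gene_ids=list(expr.index))
        assert out.labels.nunique() == expr.shape[0]

    def test_two_planted_blocks_recovered_exactly(self, two_block_expr):
        expr, truth = two_block_expr
        Z = cluster_genes(tom(adjacency(similarity(expr))))
        out = cut_modules(Z, min_module_size=30, expr=expr)
        assert len(out.modules) == 2
        assert adjusted_rand_score(truth, out.labels.to_numpy()) == 1.0

    def test_exchangeable_tom_never_splits_partially(self):
        T = pd.DataFrame(np.full((10, 10), 0.5))
        np.fill_diagonal(T.values, 1.0)
        Z = cluster_genes(T)
        out = cut_modules(Z, min_module_size=3, gene_ids=list(range(10)))
        assert out.labels.nunique() == 1  # one module or all grey, never partial

    def test_all_grey_warns(self, two_block_expr):
        expr, _ = two_block_expr
        Z = cluster_genes(tom(adjacency(similarity(expr))))
        with pytest.warns(UserWarning, match="grey"):
            out = cut_modules(Z, min_module_size=1000, cut_height=Z[:, 2].max(),
                              gene_ids=list(expr.index))
        assert out.labels.eq(GREY).all()


class TestModuleEigengenes:
    def test_rank_one_module(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame(np.vstack([2 * profile + 1, 5 * profile - 2]),
                            index=["a", "b"], columns=[f"s{i}" for i in range(5)])
        labels = pd.Series({"a": "turquoise", "b": "turquoise"})
        mes = module_eigengenes(expr, labels)
        assert mes.variance_explained["turquoise"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(mes.values.loc["turquoise"].to_numpy(), z)

    def test_sign_flip_invariance_of_trait_correlation(self, two_block_expr):
        expr, _ = two_block_expr
        labels = pd.Series(["turquoise"] * 50 + ["blue"] * 50, index=expr.index)
        trait = pd.DataFrame({"t": np.arange(expr.shape[1])}, index=expr.columns)
        me1 = module_eigengenes(expr, labels)
        flipped = expr.copy()
        flipped.iloc[:50] *= -1
        me2 = module_eigengenes(flipped, labels)
        r1 = module_trait_correlation(me1, trait).r
        r2 = module_trait_correlation(me2, trait).r
        assert abs(r1.loc["turquoise", "t"]) == pytest.approx(abs(r2.loc["turquoise", "t"]))

    def test_recovers_true_eigengene_on_synthetic_data(self, synthetic_cohort):
        expr, _, truth = synthetic_cohort
        model = WGCNA().fit(expr)
        labels = model.assignment_.labels
        for m, row in truth.eigengene_profiles.iterrows():
            mod_id = int(m.replace("module", ""))
            genes = [g for g, t in truth.true_module_of_gene.items() if t == mod_id]
            color = labels[genes].mode()[0]
            me = model.eigengenes_.values.loc[color]
            assert abs(np.corrcoef(me, row.to_numpy())[0, 1]) >= 0.95

    def test_constant_module_named_in_error(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        labels = pd.Series({"a": "blue", "b": "blue"})
        with pytest.raises(ValueError, match="blue"):
            module_eigengenes(expr, labels)


class TestMergeModules:
    def test_zero_height_is_noop(self, two_block_expr):
        expr, _ = two_block_expr
        labels = pd.Series(["turquoise"] * 50 + ["blue"] * 50, index=expr.index)
        merged, _ = merge_modules(expr, labels, merge_height=0.0)
        assert (merged == labels).all()

    def test_identical_eigengenes_merge(self, two_block_expr):
        expr, _ = two_block_expr
        # split block A into two fake modules with the same driver
        labels = pd.Series(["turquoise"] * 25 + ["blue"] * 25 + ["brown"] * 50,
                           index=expr.index)
        merged, mes = merge_modules(expr, labels, merge_height=0.25)
        assert merged[expr.index[:50]].nunique() == 1
        assert len(mes.values) == 2

    def test_never_increases_module_count(self, synthetic_cohort):
        expr, _, _ = synthetic_cohort
        model = WGCNA(merge_height=0.0).fit(expr)
        before = model.eigengenes_.values.shape[0]
        merged, mes = merge_modules(expr, model.assignment_.labels, merge_height=0.4)
        assert mes.values.shape[0] <= before


class TestModuleTraitCorrelation:
    def _mes(self, values: pd.DataFrame):
        from coexpnet.wgcna import ModuleEigengenes
        return ModuleEigengenes(values=values, variance_explained=pd.Series(dtype=float))

    def test_self_correlation(self):
        v = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0], "s4": [4.0]}, index=["m"])
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]}, index=v.columns)
        res = module_trait_correlation(self._mes(v), traits)
        assert res.r.loc["m", "t"] == pytest.approx(1.0)
        assert res.p.loc["m", "t"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_gives_p_one(self):
        n = 20
        me = np.tile([1.0, -1.0], n // 2)           # mean 0
        t = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to me
        v = pd.DataFrame([me], index=["m"], columns=[f"s{i}" for i in range(n)])
        trait = pd.DataFrame({"t": t}, index=v.columns)
        res = module_trait_correlation(self._mes(v), trait)
        assert res.r.loc["m", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.p.loc["m", "t"] == pytest.approx(1.0)

    def test_zero_variance_trait_flagged_nan(self):
        v = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["s1", "s2", "s3"])
        traits = pd.DataFrame({"const": [1, 1, 1]}, index=v.columns)
        res = module_trait_correlation(self._mes(v), traits)
        assert np.isnan(res.r.loc["m", "const"])

    def test_sample_mismatch_rejected(self):
        v = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["s1", "s2", "s3"])
        traits = pd.DataFrame({"t": [1, 2, 3]}, index=["x1", "x2", "x3"])
        with pytest.raises(ValueError):
            module_trait_correlation(self._mes(v), traits)


class TestGeneSignificance:
    def test_extremes_and_affine_invariance(self):
        trait = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame([trait, [1.0, -1.0, -1.0, 1.0]], index=["same", "orth"])
        gs = gene_significance(expr, trait)
        assert gs["same"] == pytest.approx(1.0)
        assert gs["orth"] == pytest.approx(0.0, abs=1e-12)
        gs2 = gene_significance(expr, 3.0 * trait - 7.0)
        pd.testing.assert_series_equal(gs, gs2)


class TestWGCNAEstimator:
    def test_sklearn_contract(self, synthetic_cohort):
        from sklearn.base import clone
        expr, _, _ = synthetic_cohort
        model = WGCNA(beta=3, min_module_size=30)
        params = model.get_params()
        assert params["beta"] == 3
        clone(model)  # get_params/set_params round-trip
        labels = model.fit_predict(expr)
        assert len(labels) == expr.shape[0]

    def test_recovers_planted_modules(self, synthetic_cohort):
        expr, _, truth = synthetic_cohort
        model = WGCNA().fit(expr)
        ts = pd.Series(truth.true_module_of_gene)
        ari = adjusted_rand_score(ts.values, model.assignment_.labels[ts.index].values)
        assert ari >= 0.9

    def test_deterministic(self, synthetic_cohort):
        expr, _, _ = synthetic_cohort
        m1 = WGCNA().fit(expr)
        m2 = WGCNA().fit(expr)
        assert (m1.assignment_.labels == m2.assignment_.labels).all()
        pd.testing.assert_frame_equal(m1.eigengenes_.values, m2.eigengenes_.values)
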