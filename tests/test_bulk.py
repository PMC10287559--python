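"""Bulk transcriptome operations: normalisation, filtering, embedding,
clustering, ssGSEA and differential expression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutsig import bulk

from conftest import make_expr


def make_gcm(counts: np.ndarray, biotype=None) -> bulk.GeneCountMatrix:
    genes = [f"g{i + 1}" for i in range(counts.shape[0])]
    samples = [f"s{i + 1}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"biotype": biotype or ["protein_coding"] * len(genes)}, index=genes
    )
    return bulk.GeneCountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), gene_meta=meta
    )


class TestLogCpm:
    def test_closed_form_values(self):
        counts = np.array([[0], [100]])
        counts = np.vstack([counts, [[999899]]])  # library sums to 999999
        expr = bulk.log_cpm(make_gcm(counts))
        # (0 + 0.5) / 1e6 * 1e6 = 0.5 and (100 + 0.5) -> log2(100.5)
        assert expr.values.iloc[0, 0] == pytest.approx(-1.0, abs=1e-9)
        assert expr.values.iloc[1, 0] == pytest.approx(np.log2(100.5), abs=1e-6)

    def test_depth_invariance_for_well_expressed_genes(self, rng):
        counts = rng.integers(100, 1000, size=(50, 4))
        a = bulk.log_cpm(make_gcm(counts)).values.to_numpy()
        b = bulk.log_cpm(make_gcm(counts * 2)).values.to_numpy()
        assert np.max(np.abs(a - b)) < 0.01

    def test_all_zero_sample_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s2"):
            bulk.log_cpm(make_gcm(counts))


class TestFilterGenes:
    def test_median_strictly_greater_than_five(self):
        counts = np.array([[5] * 6, [6] * 6, [100] * 6])
        gcm = make_gcm(counts, ["protein_coding", "protein_coding", "lincRNA"])
        kept = bulk.filter_genes(gcm)
        # median exactly 5 fails the strict filter; lincRNA fails biotype
        assert list(kept.gene_ids) == ["g2"]

    def test_receptor_biotypes_kept(self):
        counts = np.full((3, 4), 50)
        gcm = make_gcm(counts, ["TR_gene", "IG_gene", "other"])
        assert list(bulk.filter_genes(gcm).gene_ids) == ["g1", "g2"]

    def test_missing_biotype_errors(self):
        gcm = make_gcm(np.full((2, 2), 10))
        gcm.gene_meta = gcm.gene_meta.drop(columns="biotype")
        with pytest.raises(ValueError, match="biotype"):
            bulk.filter_genes(gcm)


class TestBatchCorrect:
    def test_single_batch_is_identity(self, rng):
        expr = make_expr(rng.normal(size=(10, 6)))
        batch = pd.Series(["b1"] * 6, index=expr.values.columns)
        out = bulk.batch_correct(expr, batch)
        np.testing.assert_allclose(out.values, expr.values, atol=1e-12)

    def test_injected_offset_removed_and_grand_mean_kept(self, rng):
        vals = rng.normal(size=(20, 8))
        vals[:, 4:] += 1.0  # +1 offset on batch B
        expr = make_expr(vals)
        batch = pd.Series(["A"] * 4 + ["B"] * 4, index=expr.values.columns)
        out = bulk.batch_correct(expr, batch).values.to_numpy()
        gap = out[:, :4].mean(axis=1) - out[:, 4:].mean(axis=1)
        np.testing.assert_allclose(gap, 0.0, atol=1e-9)
        np.testing.assert_allclose(
            out.mean(axis=1), vals.mean(axis=1), atol=1e-9
        )

    def test_singleton_batch_warns_and_keeps_values(self, rng):
        vals = rng.normal(size=(5, 5))
        expr = make_expr(vals)
        batch = pd.Series(["A"] * 4 + ["B"], index=expr.values.columns)
        with pytest.warns(UserWarning, match="singleton"):
            out = bulk.batch_correct(expr, batch)
        np.testing.assert_allclose(
            out.values.iloc[:, 4], vals[:, 4], atol=1e-9
        )


class TestSelectHvg:
    def test_inflated_variance_genes_selected(self, rng):
        # 50 genes with 10x variance at means matched to the others
        means = rng.uniform(2, 8, size=500)
        base = means[:, None] + rng.normal(0, 1, size=(500, 30))
        base[:50] = means[:50, None] + rng.normal(0, np.sqrt(10), size=(50, 30))
        expr = make_expr(base)
        hvg = bulk.select_hvg(expr, n=100)
        planted = {f"g{i + 1}" for i in range(50)}
        assert planted <= set(hvg)

    def test_constant_gene_never_selected(self, rng):
        vals = rng.normal(size=(10, 8))
        vals[3] = 2.0
        expr = make_expr(vals)
        hvg = bulk.select_hvg(expr, n=9)
        assert "g4" not in hvg and len(hvg) == 9

    def test_invalid_n(self, rng):
        expr = make_expr(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            bulk.select_hvg(expr, n=0)


class TestPcaEmbed:
    def test_rank2_input_two_pcs_explain_everything(self, rng):
        u = rng.normal(size=(10, 2))
        v = rng.normal(size=(2, 8))
        expr = make_expr((u @ v))
        with pytest.warns(UserWarning):
            model = bulk.pca_embed(expr, list(expr.values.index), n_pcs=5, scale=False)
        assert model.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_non_increasing(self, rng):
        expr = make_expr(rng.normal(size=(30, 20)))
        model = bulk.pca_embed(expr, list(expr.values.index), n_pcs=10)
        assert (np.diff(model.variance_explained) <= 1e-12).all()

    def test_full_reconstruction(self, rng):
        vals = rng.normal(size=(12, 10))
        expr = make_expr(vals)
        model = bulk.pca_embed(expr, list(expr.values.index), n_pcs=9, scale=False)
        recon = model.pc_scores.to_numpy() @ model.pc_loadings.to_numpy().T
        centered = vals.T - vals.T.mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-8)


class TestHierarchicalCluster:
    def _blob_model(self, rng):
        a = rng.normal(0, 0.2, size=(10, 3))
        b = rng.normal(5, 0.2, size=(10, 3))
        scores = pd.Series(
            np.r_[np.zeros(10), np.ones(10)], index=[f"s{i}" for i in range(20)]
        )
        pc = pd.DataFrame(
            np.vstack([a, b]), index=scores.index, columns=["PC1", "PC2", "PC3"]
        )
        model = bulk.ClusterModel(
            pc_scores=pc, pc_loadings=pd.DataFrame(), variance_explained=np.array([1.0])
        )
        return model, scores

    def test_two_blobs_recovered(self, rng):
        model, scores = self._blob_model(rng)
        out = bulk.hierarchical_cluster(model, scores, k=2)
        labels = out.labels
        assert labels.iloc[:10].nunique() == 1 and labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_sample_order_invariance(self, rng):
        model, scores = self._blob_model(rng)
        out1 = bulk.hierarchical_cluster(model, scores, k=2)
        perm = rng.permutation(20)
        model2 = bulk.ClusterModel(
            pc_scores=model.pc_scores.iloc[perm],
            pc_loadings=model.pc_loadings,
            variance_explained=model.variance_explained,
        )
        out2 = bulk.hierarchical_cluster(model2, scores.iloc[perm], k=2)
        assert (out2.labels.reindex(out1.labels.index) == out1.labels).all()

    def test_k_larger_than_n_errors(self, rng):
        model, scores = self._blob_model(rng)
        with pytest.raises(ValueError):
            bulk.hierarchical_cluster(model, scores, k=21)


def ssgsea_oracle(values: np.ndarray, genes: list, gene_set: set, alpha: float) -> float:
    """Direct running-sum computation for one sample."""
    order = np.argsort(-values, kind="stable")
    n = len(genes)
    in_set = [genes[i] in gene_set for i in order]
    n_in = sum(in_set)
    weights = [(n - pos) ** alpha for pos in range(n)]
    denom = sum(w for w, s in zip(weights, in_set) if s)
    running, total = 0.0, 0.0
    for pos in range(n):
        if in_set[pos]:
            running += weights[pos] / denom
        else:
            running -= 1.0 / (n - n_in)
        total += running
    return total / n


class TestSsgsea:
    def test_matches_direct_oracle(self, rng):
        vals = rng.normal(size=(20, 5))
        expr = make_expr(vals)
        gene_set = {"g3", "g7", "g11", "g18"}
        scores = bulk.ssgsea_score(expr, sorted(gene_set))
        for j, s in enumerate(expr.values.columns):
            expected = ssgsea_oracle(
                vals[:, j], list(expr.values.index), gene_set, 0.25
            )
            assert scores[s] == pytest.approx(expected, abs=1e-12)

    def test_top_placement_is_maximal(self):
        # a set occupying the top |S| ranks beats every other placement
        genes = [f"g{i + 1}" for i in range(10)]
        vals = np.arange(10, 0, -1, dtype=float).reshape(-1, 1)
        expr = make_expr(vals, genes=genes)
        sample = expr.values.columns[0]
        top = bulk.ssgsea_score(expr, genes[:3])[sample]
        for placement in itertools.combinations(range(10), 3):
            score = bulk.ssgsea_score(expr, [genes[i] for i in placement])[sample]
            assert score <= top + 1e-12

    def test_all_genes_degenerate_score_zero(self, rng):
        expr = make_expr(rng.normal(size=(6, 3)))
        scores = bulk.ssgsea_score(expr, list(expr.values.index))
        assert (scores == 0).all()

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=(15, 4))
        expr1 = make_expr(vals)
        expr2 = make_expr(np.exp(vals))
        s1 = bulk.ssgsea_score(expr1, ["g2", "g9"])
        s2 = bulk.ssgsea_score(expr2, ["g2", "g9"])
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_empty_intersection_errors(self, rng):
        expr = make_expr(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            bulk.ssgsea_score(expr, ["absent"])


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up adjustment."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        adj[i] = running_min
    return adj


class TestBh:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 100))
        np.testing.assert_allclose(bulk.bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_brute_force_and_monotonicity_properties(self, pvals):
        p = np.asarray(pvals)
        adj = bulk.bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= p - 1e-15).all()
        # adjusted values preserve the raw p ranking
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestDifferentialExpression:
    def test_classical_t_without_moderation(self, rng):
        Y = rng.normal(size=(30, 12))
        expr = make_expr(Y)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=expr.values.columns)
        de = bulk.differential_expression(expr, groups, ("A", "B"), prior_df=0)
        for g in range(30):
            t_ref = stats.ttest_ind(Y[g, :6], Y[g, 6:], equal_var=True).statistic
            assert de["t"].iloc[g] == pytest.approx(t_ref, abs=1e-8)

    def test_null_rejection_rate(self):
        fracs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Y = rng.normal(size=(200, 20))
            expr = make_expr(Y)
            groups = pd.Series(["A"] * 10 + ["B"] * 10, index=expr.values.columns)
            de = bulk.differential_expression(expr, groups, ("A", "B"))
            fracs.append((de["pvalue"] < 0.05).mean())
        assert 0.01 <= np.mean(fracs) <= 0.12

    def test_power_for_planted_effect(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Y = rng.normal(0, 0.5, size=(100, 40))
            Y[0, :20] += 2.0  # delta = 2 log2 units in group A
            expr = make_expr(Y)
            groups = pd.Series(["A"] * 20 + ["B"] * 20, index=expr.values.columns)
            de = bulk.differential_expression(expr, groups, ("A", "B"))
            hits += de["adj_pvalue"].iloc[0] < 0.05
        assert hits >= 19

    def test_confounded_design_rejected(self, rng):
        Y = rng.normal(size=(10, 8))
        expr = make_expr(Y)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=expr.values.columns)
        cov = pd.DataFrame(
            {"batch": ["x"] * 4 + ["y"] * 4}, index=expr.values.columns
        )
        with pytest.raises(ValueError, match="confounded"):
            bulk.differential_expression(expr, groups, ("A", "B"), covariates=cov)
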