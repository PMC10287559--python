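"""DP-cell analysis: size factors, flow calibration, scoring, enrichment,
pseudobulk differential expression."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import fisher_exact

from gutsig import dp_cells, synthetic


def make_cells(counts: np.ndarray, genes=None, sample_ids=None) -> dp_cells.CellCountMatrix:
    genes = genes or [f"g{i + 1}" for i in range(counts.shape[0])]
    cells = [f"c{i + 1:04d}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids or ["S1"] * len(cells),
            "patient_cluster": "I2",
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return dp_cells.CellCountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cells), cell_meta=meta
    )


class TestSizeFactors:
    def test_identical_cells_get_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [30], [5]]), (1, 60))
        fac, filt = dp_cells.compute_size_factors(make_cells(counts))
        np.testing.assert_allclose(fac, 1.0, atol=1e-6)
        assert filt.counts.shape[1] == 60

    def test_extreme_cell_removed(self, rng):
        base = rng.poisson(5, size=(50, 80)) + 1
        base[:, 0] *= 100  # one cell with ~100x everyone's counts
        fac, filt = dp_cells.compute_size_factors(make_cells(base))
        assert "c0001" not in filt.counts.columns
        assert (fac > 0).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="50"):
            dp_cells.compute_size_factors(make_cells(np.ones((5, 10))))


class TestCalibration:
    def _cells_with_dp(self, n=400, dp_frac=0.05):
        rng = np.random.default_rng(0)
        counts = np.zeros((3, n), dtype=int)
        n_dp = int(round(dp_frac * n))
        counts[0, :n_dp] = 1  # IL17A
        counts[1, :n_dp] = 1  # FOXP3
        counts[2] = rng.poisson(5, n)  # filler gene
        return make_cells(counts, genes=["IL17A", "FOXP3", "other"])

    def test_exact_match_picks_threshold_one(self):
        cells = self._cells_with_dp()
        flow = pd.DataFrame({"dp_freq": [0.05]}, index=pd.Index(["S1"], name="sample_id"))
        labels, t = dp_cells.calibrate_dp_threshold(cells, flow)
        assert t == 1
        assert (labels == "DP").mean() == pytest.approx(0.05)

    def test_zero_target_minimises_dp_set(self):
        # strictly positive DP freq at every threshold -> maximal t chosen
        rng = np.random.default_rng(1)
        counts = np.zeros((2, 300), dtype=int)
        counts[0] = rng.integers(1, 30, 300)
        counts[1] = rng.integers(1, 30, 300)
        cells = make_cells(counts, genes=["IL17A", "FOXP3"])
        flow = pd.DataFrame({"dp_freq": [0.0]}, index=pd.Index(["S1"], name="sample_id"))
        freqs = [
            ((counts[0] >= t) & (counts[1] >= t)).mean() for t in range(1, 11)
        ]
        assert all(f > 0 for f in freqs) and freqs == sorted(freqs, reverse=True)
        labels, t = dp_cells.calibrate_dp_threshold(cells, flow)
        assert t == 10

    def test_labels_partition_cells(self):
        cells = self._cells_with_dp()
        flow = pd.DataFrame({"dp_freq": [0.05]}, index=pd.Index(["S1"], name="sample_id"))
        labels, _ = dp_cells.calibrate_dp_threshold(cells, flow)
        assert set(labels.unique()) <= set(dp_cells.SUBSETS)
        assert len(labels) == cells.counts.shape[1]

    def test_missing_flow_row_errors(self):
        cells = self._cells_with_dp()
        flow = pd.DataFrame({"dp_freq": [0.05]}, index=pd.Index(["S9"], name="sample_id"))
        with pytest.raises(ValueError, match="S1"):
            dp_cells.calibrate_dp_threshold(cells, flow)


class TestPathogenicScore:
    def test_all_zero_cell_has_minimal_score(self, rng):
        counts = rng.poisson(5, size=(10, 60)) + 1
        counts[:, 0] = 0
        cells = make_cells(counts)
        score = dp_cells.pathogenic_score(cells, [f"g{i + 1}" for i in range(10)])
        assert score.iloc[0] == score.min()

    def test_planted_dp_shift_orders_means(self):
        for seed in range(20):
            cfg = synthetic.SimConfig(seed=seed, sc_n_cells=600)
            cells, _ = synthetic.simulate_cd4_cells(cfg)
            score = dp_cells.pathogenic_score(cells, synthetic.SIGNATURE_PANEL)
            truth = cells.cell_meta["true_subset"]
            assert score[truth == "DP"].mean() > score[truth != "DP"].mean()

    def test_empty_signature_errors(self, rng):
        cells = make_cells(rng.poisson(2, size=(4, 60)))
        with pytest.raises(ValueError):
            dp_cells.pathogenic_score(cells, ["missing"])


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exhaustive two-sided Fisher p by enumerating tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {x: table_prob(x) for x in range(lo, hi + 1)}
    total = sum(probs.values())
    cutoff = probs[a]
    # scipy-style relative tolerance for "as extreme"
    p = sum(v for v in probs.values() if v <= cutoff * (1 + 1e-7))
    return p / total


class TestDecileEnrichment:
    def test_hand_computed_sample_odds_ratio(self):
        # direct construction of the 2x2 [[10, 90], [5, 95]]
        n = 200
        cells = [f"c{i:03d}" for i in range(n)]
        scores = pd.Series(np.arange(n, dtype=float), index=cells)
        labels = pd.Series("DN", index=cells)
        top = scores.sort_values().index[-20:]
        bottom = scores.sort_values().index[:20]
        labels[top[:2]] = "DP"
        labels[bottom[:1]] = "DP"
        res = dp_cells.decile_enrichment(scores, labels)[0]
        a, b = res.contingency[0]
        c, d = res.contingency[1]
        assert (a, b, c, d) == (2, 18, 1, 19)
        assert res.odds_ratio == pytest.approx((2 * 19) / (18 * 1))

    def test_sample_or_formula_on_given_table(self):
        table = np.array([[10, 90], [5, 95]])
        assert (10 * 95) / (90 * 5) == pytest.approx(2.111, abs=1e-3)
        res = fisher_exact(table)
        # conditional-MLE OR close to but distinct from the sample OR
        from scipy.stats.contingency import odds_ratio

        cmle = odds_ratio(table).statistic
        assert 1.5 < cmle < 3.0

    @pytest.mark.parametrize("margins", [(6, 8, 7), (10, 10, 10), (12, 18, 9)])
    def test_fisher_matches_enumeration_oracle(self, margins):
        r1, r2, c1 = margins
        lo = max(0, c1 - r2)
        hi = min(r1, c1)
        for a in range(lo, hi + 1):
            b = r1 - a
            c = c1 - a
            d = r2 - c
            p_scipy = dp_cells.fisher_exact_p(np.array([[a, b], [c, d]]))
            p_oracle = fisher_two_sided_oracle(a, b, c, d)
            assert p_scipy == pytest.approx(p_oracle, rel=1e-6)

    def test_degenerate_table_infinite_or(self):
        n = 100
        cells = [f"c{i:03d}" for i in range(n)]
        scores = pd.Series(np.arange(n, dtype=float), index=cells)
        labels = pd.Series("DN", index=cells)
        labels[scores.sort_values().index[-10:]] = "DP"  # all DP in top decile
        res = dp_cells.decile_enrichment(scores, labels)[0]
        assert res.odds_ratio == np.inf
        assert 0 < res.fisher_p < 1e-4

    def test_decile_sizes_within_one_cell(self, rng):
        for n in (95, 100, 104):
            cells = [f"c{i:03d}" for i in range(n)]
            scores = pd.Series(rng.normal(size=n), index=cells)
            top, bottom = dp_cells._decile_sets(scores)
            assert abs(len(top) - 0.1 * n) <= 1
            assert abs(len(bottom) - 0.1 * n) <= 1

    def test_null_rejection_rate(self):
        rej = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            scores = pd.Series(
                rng.normal(size=2000), index=[f"c{i:04d}" for i in range(2000)]
            )
            labels = pd.Series(
                np.where(rng.random(2000) < 0.25, "DP", "DN"), index=scores.index
            )
            res = dp_cells.decile_enrichment(scores, labels)[0]
            rej += res.fisher_p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_stratified_runs_per_cluster(self, rng):
        n = 300
        cells = [f"c{i:03d}" for i in range(n)]
        scores = pd.Series(rng.normal(size=n), index=cells)
        labels = pd.Series(np.where(rng.random(n) < 0.3, "DP", "DN"), index=cells)
        strat = pd.Series(np.where(np.arange(n) < 150, "I2", "U"), index=cells)
        results = dp_cells.decile_enrichment(scores, labels, stratify_by=strat)
        assert {r.stratum for r in results} == {"I2", "U"}


class TestPseudobulkDe:
    def _cells(self, n_patients=6, cells_per=100, delta=1.5, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i + 1}" for i in range(40)]
        cols, meta, labels = {}, [], {}
        for p in range(n_patients):
            for c in range(cells_per):
                cid = f"p{p}_c{c:03d}"
                sub = "DP" if c < cells_per // 2 else "SP"
                lam = np.full(40, 4.0)
                if sub == "DP":
                    lam[0] *= 2**delta
                cols[cid] = rng.poisson(lam)
                meta.append((cid, f"p{p}", "I2"))
                labels[cid] = sub
        counts = pd.DataFrame(cols, index=genes)
        meta_df = pd.DataFrame(
            meta, columns=["cell_id", "sample_id", "patient_cluster"]
        ).set_index("cell_id")
        return (
            dp_cells.CellCountMatrix(counts=counts, cell_meta=meta_df),
            pd.Series(labels),
        )

    def test_pseudobulk_of_identical_cells_is_the_profile(self):
        counts = np.tile(np.array([[2], [8]]), (1, 30))
        cells = make_cells(counts)
        labels = pd.Series(
            ["DP"] * 15 + ["SP"] * 15, index=cells.counts.columns
        )
        logn = dp_cells.normalized_log(cells, pd.Series(1.0, index=cells.counts.columns))
        # every cell identical -> pseudobulk means equal per-cell log profile
        assert logn.nunique(axis=1).max() == 1

    def test_hand_mean_of_two_cells(self):
        vals = pd.DataFrame({"c1": [1.0], "c2": [3.0]}, index=["g1"])
        assert vals.mean(axis=1).iloc[0] == 2.0

    def test_planted_effect_detected(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cells, labels = self._cells(seed=seed)
            de = dp_cells.pseudobulk_de(cells, labels, contrast=("DP", "SP"))
            hits += de.loc["g1", "adj_pvalue"] < 0.1
        assert hits >= 9

    def test_subset_in_too_few_patients_rejected(self):
        cells, labels = self._cells(n_patients=1, cells_per=60)
        with pytest.raises(ValueError, match="fewer than 2"):
            dp_cells.pseudobulk_de(cells, labels, contrast=("DP", "SP"))
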