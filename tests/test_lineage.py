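"""Spearman machinery, marker discovery, lineage scoring and fate calls."""
import itertools

import numpy as np
import pandas as pd
import pytest

import scqpcr as sq
from scqpcr.data import ExpressionMatrix, MarkerSets, PipelineError
from scqpcr.lineage import (
    FOUR_GENE_PANEL,
    assign_fate,
    cluster_correlation,
    evaluate_panel,
    exact_spearman_pvalue,
    extract_marker_sets,
    lineage_score,
    spearman_matrix,
)
from _helpers import brute_spearman


def expr_from(values: pd.DataFrame, censored: pd.DataFrame | None = None):
    if censored is None:
        censored = pd.DataFrame(False, index=values.index, columns=values.columns)
    return ExpressionMatrix(values=values.astype(float), censored=censored,
                            reference_ids=[])


def frame(rows: dict[str, list]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"c{i}" for i in range(df.shape[1])]
    return df


class TestSpearmanMatrix:
    def test_perfect_monotone_pairs(self):
        values = frame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10],
                        "c": [5, 4, 3, 2, 1]})
        corr = spearman_matrix(expr_from(values))
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)
        assert corr.rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            X = rng.normal(size=(10, 10))
            values = pd.DataFrame(X, index=[f"g{i}" for i in range(10)])
            corr = spearman_matrix(expr_from(values))
            assert np.allclose(corr.rho.to_numpy(), brute_spearman(X), atol=1e-12)

    def test_exact_pvalue_matches_full_enumeration_frozen(self):
        # rho = 23/35; 126 of the 720 orderings reach |rho| >= 23/35
        x = np.arange(1, 7)
        y = np.array([3, 1, 2, 5, 6, 4])
        assert exact_spearman_pvalue(x, y) == pytest.approx(126 / 720)

    def test_exact_pvalue_matches_scipy_enumeration(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        obs = abs(spearmanr(x, y).statistic)
        hits = sum(abs(spearmanr(x, p).statistic) >= obs - 1e-12
                   for p in itertools.permutations(y))
        assert exact_spearman_pvalue(x, y) == pytest.approx(hits / 120)

    def test_small_n_uses_exact_enumeration(self):
        values = frame({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5],
                        "c": [3, 3, 3, 3, 3]})
        corr = spearman_matrix(expr_from(values), exact_cutoff=7)
        assert corr.pvalue.loc["a", "b"] == pytest.approx(
            exact_spearman_pvalue(np.arange(5), np.array([2, 1, 4, 3, 5])))

    def test_constant_rows_flagged(self):
        values = frame({"a": [1, 2, 3, 4, 5], "b": [7, 7, 7, 7, 7]})
        corr = spearman_matrix(expr_from(values))
        assert corr.constant_genes == ["b"]
        assert corr.rho.loc["a", "b"] == 0.0
        assert corr.pvalue.loc["a", "b"] == 1.0

    def test_mostly_censored_genes_flagged(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        censored = pd.DataFrame(False, index=values.index, columns=values.columns)
        censored.loc["c", values.columns[:8]] = True
        corr = spearman_matrix(expr_from(values, censored))
        assert corr.low_detection_genes == ["c"]
        assert corr.rho.loc["a", "c"] == 0.0

    def test_too_few_cells_rejected(self):
        values = frame({"a": [1, 2, 3], "b": [1, 2, 3]})
        with pytest.raises(PipelineError, match="4"):
            spearman_matrix(expr_from(values))


def block_correlation(n_a=4, n_b=3):
    """Two perfectly anti-correlated blocks of genes."""
    up = np.arange(8, dtype=float)
    rows = {f"a{i}": up + i for i in range(n_a)}
    rows.update({f"b{i}": -up - i for i in range(n_b)})
    return spearman_matrix(expr_from(frame(rows)))


class TestCorrelationClustering:
    def test_perfect_blocks_resolve_into_two_clusters(self):
        corr = block_correlation()
        labels = cluster_correlation(corr)
        assert labels.nunique() == 2
        assert labels[[f"a{i}" for i in range(4)]].nunique() == 1
        assert labels[[f"b{i}" for i in range(3)]].nunique() == 1

    def test_single_gene_is_a_singleton(self):
        values = frame({"a": [1, 2, 3, 4]})
        corr = spearman_matrix(expr_from(values))
        labels = cluster_correlation(corr)
        assert list(labels) == [1]


class TestMarkerExtraction:
    def test_perfect_blocks_become_marker_sets(self):
        corr = block_correlation()
        labels = cluster_correlation(corr, k=2)
        sets = extract_marker_sets(labels, corr, anchors=("a0",))
        assert sets.icm == [f"a{i}" for i in range(4)]
        assert sets.te == [f"b{i}" for i in range(3)]
        assert sets.between_mean_rho == pytest.approx(-1.0)

    def test_all_positive_correlations_rejected(self):
        up = np.arange(8, dtype=float)
        rows = {f"g{i}": up * (i + 1) + i for i in range(6)}
        corr = spearman_matrix(expr_from(frame(rows)))
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=corr.rho.index)
        with pytest.raises(PipelineError, match="anti-correlated"):
            extract_marker_sets(labels, corr)

    def test_anchorless_sets_flagged(self):
        corr = block_correlation()
        labels = cluster_correlation(corr, k=2)
        sets = extract_marker_sets(labels, corr, anchors=("Pou5f1",))
        assert not sets.anchored

    def test_disjointness_enforced(self):
        with pytest.raises(PipelineError, match="overlap"):
            MarkerSets(icm=["a"], te=["a"], within_icm_mean_rho=1.0,
                       within_te_mean_rho=1.0, between_mean_rho=-1.0)


class TestLineageScore:
    sets = MarkerSets(icm=["i1", "i2"], te=["t1", "t2"],
                      within_icm_mean_rho=0.9, within_te_mean_rho=0.9,
                      between_mean_rho=-0.9)

    def expr(self):
        return expr_from(frame({
            "i1": [2, -4, 1], "i2": [2, -4, -1],
            "t1": [-4, 2, 1], "t2": [-4, 2, -1],
        }))

    def test_worked_example(self):
        score = lineage_score(self.expr(), self.sets)
        assert score["c0"] == pytest.approx(6.0)
        assert score["c1"] == pytest.approx(-6.0)
        assert score["c2"] == pytest.approx(0.0)

    def test_antisymmetric_under_set_swap(self):
        swapped = MarkerSets(icm=self.sets.te, te=self.sets.icm,
                             within_icm_mean_rho=0.9, within_te_mean_rho=0.9,
                             between_mean_rho=-0.9)
        a = lineage_score(self.expr(), self.sets)
        b = lineage_score(self.expr(), swapped)
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_shift_invariance_and_equivariance(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(size=(4, 6)),
                              index=["i1", "i2", "t1", "t2"],
                              columns=[f"c{i}" for i in range(6)])
        base = lineage_score(expr_from(values), self.sets)
        both = lineage_score(expr_from(values + 3.0), self.sets)
        assert np.allclose(base.to_numpy(), both.to_numpy())
        shifted = values.copy()
        shifted.loc[["i1", "i2"]] += 2.5
        icm_only = lineage_score(expr_from(shifted), self.sets)
        assert np.allclose(icm_only.to_numpy(), base.to_numpy() + 2.5)

    def test_missing_gene_named_in_error(self):
        expr = expr_from(frame({"i1": [1, 2], "t1": [2, 1]}))
        sets = MarkerSets(icm=["i1", "ghost"], te=["t1"],
                          within_icm_mean_rho=0.5, within_te_mean_rho=0.5,
                          between_mean_rho=-0.5)
        with pytest.raises(PipelineError, match="ghost"):
            lineage_score(expr, sets)


class TestFateCalls:
    sets = TestLineageScore.sets

    def test_fixed_threshold_rules(self):
        expr = expr_from(frame({
            "i1": [2, 0, -4], "i2": [2, 0, -4],
            "t1": [-4, 0, 2], "t2": [-4, 0, 2],
        }))
        calls = assign_fate(expr, self.sets, thresholds=(-1.0, 1.0))
        assert calls.fate["c0"] == "ICM"
        assert calls.fate["c1"] == "n.d."
        assert calls.fate["c2"] == "TE"

    def test_swap_equivariance_with_symmetric_thresholds(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(scale=3, size=(4, 20)),
                              index=["i1", "i2", "t1", "t2"],
                              columns=[f"c{i}" for i in range(20)])
        swapped = MarkerSets(icm=self.sets.te, te=self.sets.icm,
                             within_icm_mean_rho=0.9, within_te_mean_rho=0.9,
                             between_mean_rho=-0.9)
        a = assign_fate(expr_from(values), self.sets, thresholds=(-1.5, 1.5))
        b = assign_fate(expr_from(values), swapped, thresholds=(-1.5, 1.5))
        flip = {"ICM": "TE", "TE": "ICM", "n.d.": "n.d."}
        assert (a.fate.map(flip) == b.fate).all()

    def test_set_means_mode_requires_opposing_levels(self):
        expr = expr_from(frame({
            "i1": [3, 3, -5], "i2": [3, 3, -5],
            "t1": [-5, 3, 3], "t2": [-5, 3, 3],
        }))
        calls = assign_fate(expr, self.sets, mode="set_means")
        assert calls.fate["c0"] == "ICM"
        assert calls.fate["c1"] == "n.d."  # both sets high: undefined
        assert calls.fate["c2"] == "TE"

    def test_noiseless_fates_match_planted_truth(self, noiseless_run):
        result, _, truth = noiseless_run
        fc = result.fate_calls
        assert (fc.fate == truth.cell_fate.loc[fc.fate.index]).all()
        assert (fc.fate != "n.d.").all()


class TestPanelEvaluation:
    def test_full_icm_set_is_self_consistent(self, noiseless_run):
        result, smeta, _ = noiseless_run
        blast = sq.select_blastomeres(result.expression,
                                      smeta.loc[result.expression.samples])
        conc = evaluate_panel(blast, result.marker_sets.icm, result.fate_calls,
                              sets=result.marker_sets)
        assert conc == pytest.approx(1.0)

    def test_four_gene_panel_recovers_fates(self, default_run):
        result, smeta, _ = default_run
        blast = sq.select_blastomeres(result.expression,
                                      smeta.loc[result.expression.samples])
        conc = evaluate_panel(blast, list(FOUR_GENE_PANEL), result.fate_calls,
                              sets=result.marker_sets)
        assert conc >= 0.9

    def test_uninformative_panel_near_chance(self, default_run):
        result, smeta, truth = default_run
        blast = sq.select_blastomeres(result.expression,
                                      smeta.loc[result.expression.samples])
        flat = [g for g in truth.gene_class.index[
            truth.gene_class == "ubiquitous"] if g in blast.values.index][:1]
        conc = evaluate_panel(blast, flat, result.fate_calls,
                              sets=result.marker_sets)
        # chance distribution from permuted fate labels
        rng = np.random.default_rng(0)
        fc = result.fate_calls
        null = []
        for _ in range(200):
            perm = pd.Series(rng.permutation(fc.fate.to_numpy()),
                             index=fc.fate.index)
            permuted = sq.FateCalls(score=fc.score, fate=perm,
                                    thresholds=fc.thresholds)
            null.append(evaluate_panel(blast, flat, permuted,
                                       sets=result.marker_sets))
        lo, hi = np.percentile(null, [1, 99])
        assert lo <= conc <= hi

    def test_empty_panel_rejected(self, default_run):
        result, smeta, _ = default_run
        blast = sq.select_blastomeres(result.expression,
                                      smeta.loc[result.expression.samples])
        with pytest.raises(PipelineError, match="empty"):
            evaluate_panel(blast, [], result.fate_calls)
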