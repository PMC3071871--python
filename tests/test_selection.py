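"""Cutoff selection, rank-stability and core-set robustness diagnostics."""

import math

import numpy as np
import pytest

import depgenes as dg
from depgenes.errors import ValidationError


class TestSelectDepgenes:
    def test_fixture_at_published_cutoff(self):
        table = dg.load_fixture_depgenes()
        scores = dict(zip(table.genes, table.combined_scores))
        assert len(dg.select_depgenes(scores, 15.0)) == 169

    def test_cutoff_above_maximum_empty(self):
        table = dg.load_fixture_depgenes()
        scores = dict(zip(table.genes, table.combined_scores))
        assert len(dg.select_depgenes(scores, 48.0)) == 0

    def test_cutoff_zero_keeps_positive_scores(self):
        scores = {"A": 5.0, "B": 1.0, "C": 3.0}
        assert len(dg.select_depgenes(scores, 0.0)) == 3

    def test_antitone_in_cutoff(self):
        rng = np.random.default_rng(1)
        scores = {f"G{i}": float(s) for i, s in enumerate(rng.uniform(0.1, 50, 200))}
        previous = None
        for cutoff in (0.0, 5.0, 15.0, 30.0, 45.0):
            selected = set(dg.select_depgenes(scores, cutoff).genes)
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_sorted_descending_with_symbol_ties(self):
        table = dg.select_depgenes({"B": 2.0, "A": 2.0, "C": 9.0}, 1.0)
        assert table.genes == ("C", "A", "B")


class TestSuggestCutoff:
    def test_perfect_separation(self):
        diags = dg.suggest_cutoff([20.0, 20.0], [5.0, 5.0, 5.0], grid=[10.0])
        assert diags[0].separation == pytest.approx(1.0)
        assert dg.choose_cutoff(diags) == 10.0

    def test_identical_distributions_near_zero_separation(self):
        vals = list(np.linspace(1, 10, 50))
        diags = dg.suggest_cutoff(vals, vals)
        assert max(abs(d.separation) for d in diags) == pytest.approx(0.0)

    def test_bimodal_mixture_cutoff_lands_in_gap(self):
        rng = np.random.default_rng(3)
        low = rng.uniform(0, 8, 300)
        high = rng.uniform(20, 30, 40)
        core = rng.uniform(20, 30, 10)
        diags = dg.suggest_cutoff(
            core, np.concatenate([low, high]), grid=np.linspace(0, 30, 301)
        )
        best = dg.choose_cutoff(diags)
        # separation is maximal anywhere above the background mode while all
        # core genes are still retained
        assert low.max() <= best <= core.min()

    def test_tie_goes_to_smallest_cutoff(self):
        diags = dg.suggest_cutoff([20.0, 21.0], [1.0, 2.0], grid=[5.0, 10.0])
        assert diags[0].separation == diags[1].separation == 1.0
        assert dg.choose_cutoff(diags) == 5.0


class TestRankCorrelation:
    def test_identical_matrices_correlate_perfectly(self, toy_matrix, uniform_preweight):
        w = dg.WeightVector((2, 1, 1, 3, 1, 1, 2))
        rho, mean = dg.rank_correlation([w, w], toy_matrix, uniform_preweight)
        assert mean == pytest.approx(1.0)
        np.testing.assert_allclose(rho, np.ones((2, 2)))

    def test_reversed_ranking_gives_minus_one(self, uniform_preweight):
        # linkage ascending, pathway descending: up-weighting pathway reverses
        scores = np.zeros((4, 7))
        scores[:, 1] = [1.0, 2.0, 3.0, 4.0]
        scores[:, 4] = [4.0, 3.0, 2.0, 1.0]
        matrix = dg.EvidenceMatrix(("A", "B", "C", "D"), scores)
        w_link = dg.WeightVector((1, 8, 1, 1, 1, 1, 1))
        w_path = dg.WeightVector((1, 1, 1, 1, 8, 1, 1))
        _, mean = dg.rank_correlation([w_link, w_path], matrix, uniform_preweight)
        assert mean == pytest.approx(-1.0)

    def test_matches_direct_spearman_formula_on_distinct_ranks(self, uniform_preweight):
        rng = np.random.default_rng(9)
        scores = np.zeros((5, 7))
        scores[:, 0] = rng.permutation([1.0, 2.0, 3.0, 4.0, 5.0])
        scores[:, 3] = rng.permutation([1.0, 2.0, 3.0, 4.0, 5.0])
        matrix = dg.EvidenceMatrix(tuple("ABCDE"), scores)
        w_a = dg.WeightVector((8, 1, 1, 1, 1, 1, 1))
        w_b = dg.WeightVector((1, 1, 1, 8, 1, 1, 1))
        rho, mean = dg.rank_correlation([w_a, w_b], matrix, uniform_preweight)
        # 1 - 6*sum(d^2)/(n(n^2-1)) on the two injected permutations
        ranks_a = np.argsort(np.argsort(-scores[:, 0] * 8 - scores[:, 3]))
        ranks_b = np.argsort(np.argsort(-scores[:, 3] * 8 - scores[:, 0]))
        d2 = ((ranks_a - ranks_b) ** 2).sum()
        expected = 1 - 6 * d2 / (5 * 24)
        assert mean == pytest.approx(expected)
        np.testing.assert_allclose(rho, rho.T)

    def test_matches_scipy_spearmanr_on_three_matrices(self, uniform_preweight):
        rng = np.random.default_rng(15)
        scores = np.where(rng.random((12, 7)) < 0.6, rng.uniform(0, 5, (12, 7)), 0.0)
        matrix = dg.EvidenceMatrix(tuple(f"G{i:02d}" for i in range(12)), scores)
        ws = [dg.WeightVector(tuple(v)) for v in ((1,) * 7, (2, 1, 1, 3, 1, 1, 2), (1, 4, 1, 1, 2, 1, 1))]
        rho, _ = dg.rank_correlation(ws, matrix, uniform_preweight)
        from scipy.stats import spearmanr

        cols = np.stack(
            [matrix.scores @ (uniform_preweight.as_array() * w.as_array()) for w in ws],
            axis=1,
        )
        np.testing.assert_allclose(rho, spearmanr(cols).statistic, atol=1e-12)

    def test_needs_two_matrices(self, toy_matrix, uniform_preweight):
        with pytest.raises(ValidationError):
            dg.rank_correlation([dg.WeightVector((1,) * 7)], toy_matrix, uniform_preweight)


class TestCompareCoreSets:
    @staticmethod
    def _planted_matrix():
        """Two disjoint gene blocks, each strong in a different source.

        Block A leads under unit weights; block B overtakes only when animal
        expression is up-weighted, so the two core sets genuinely select
        different matrices.
        """
        rng = np.random.default_rng(21)
        n = 40
        scores = np.where(rng.random((n, 7)) < 0.1, rng.uniform(0, 0.4, (n, 7)), 0.0)
        scores[:8, 0] = rng.uniform(3.5, 4.0, 8)       # block A: association
        scores[8:16, 5] = rng.uniform(3.0, 3.4, 8)     # block B: animal expression
        genes = tuple(f"G{i:02d}" for i in range(n))
        return dg.EvidenceMatrix(genes, scores)

    def test_same_core_sets_fully_overlap(self, uniform_preweight):
        matrix = self._planted_matrix()
        core = dg.CoreGeneSet(("G00", "G01", "G02"))
        grid = list(dg.enumerate_weight_vectors(7, 2))
        report = dg.compare_core_sets(
            matrix, uniform_preweight, grid, core, core, phi=0.9, eta=0.3, cutoff=3.0
        )
        assert set(report.overlap) == set(report.depgenes_a.genes)
        assert report.depgenes_a.genes == report.depgenes_b.genes

    def test_disjoint_cores_partial_overlap(self, uniform_preweight):
        matrix = self._planted_matrix()
        core_a = dg.CoreGeneSet(("G00", "G01", "G02"))
        core_b = dg.CoreGeneSet(("G08", "G09", "G10"))
        grid = list(dg.enumerate_weight_vectors(7, 2))
        report = dg.compare_core_sets(
            matrix, uniform_preweight, grid, core_a, core_b, phi=0.9, eta=0.3, cutoff=6.0
        )
        assert len(report.overlap) < len(report.depgenes_a)
        assert len(report.overlap) < len(report.depgenes_b)
        assert np.isfinite(report.mean_score_b_only)

    def test_empty_grid_rejected(self, toy_matrix, uniform_preweight):
        core = dg.CoreGeneSet(("GENEA", "GENEB"))
        with pytest.raises(ValidationError):
            dg.compare_core_sets(
                toy_matrix, uniform_preweight, [], core, core, 0.9, 0.3, 1.0
            )
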