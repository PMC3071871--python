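"""Combined scores, grid enumeration, ranking and matrix selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import depgenes as dg
from depgenes.errors import ValidationError


class TestCombinedScore:
    def test_zero_scores_give_zero(self, preweight):
        w = dg.WeightVector((5, 1, 2, 8, 1, 1, 3))
        assert dg.combined_score([0.0] * 7, w, preweight) == 0.0

    def test_optimal_matrix_effective_multipliers(self, preweight):
        w = dg.WeightVector(dg.OPTIMAL_WEIGHT_MATRIX)
        assert dg.effective_weights(w, preweight) == (3, 1, 1.5, 4, 1, 1, 3.5)

    def test_all_ones_scores_sum_effective_weights(self, preweight):
        w = dg.WeightVector(dg.OPTIMAL_WEIGHT_MATRIX)
        assert dg.combined_score([1.0] * 7, w, preweight) == pytest.approx(15.0)

    def test_length_mismatch_raises(self, preweight):
        with pytest.raises(ValidationError):
            dg.combined_score([1.0] * 6, dg.WeightVector((1,) * 7), preweight)


class TestEnumeration:
    def test_single_source(self):
        vecs = [w.values for w in dg.enumerate_weight_vectors(1, 2)]
        assert vecs == [(1,), (2,)]

    def test_two_sources_three_levels_lexicographic(self):
        vecs = [w.values for w in dg.enumerate_weight_vectors(2, 3)]
        assert len(vecs) == 9
        assert vecs[0] == (1, 1)
        assert vecs[-1] == (3, 3)
        assert vecs == sorted(vecs)

    @pytest.mark.parametrize("n,d", [(1, 8), (3, 3), (4, 2), (5, 4), (7, 2)])
    def test_cardinality_is_d_to_the_n(self, n, d):
        assert sum(1 for _ in dg.enumerate_weight_vectors(n, d)) == d**n

    def test_weight_vector_validation(self):
        with pytest.raises(ValidationError):
            dg.WeightVector((0, 1, 1, 1, 1, 1, 1))


class TestRankGenes:
    def test_descending_with_symbol_tiebreak(self, toy_matrix, uniform_preweight):
        w = dg.WeightVector((1,) * 7)
        ranking = dg.rank_genes(toy_matrix, w, uniform_preweight)
        # GENEA and GENEB tie at 13; A comes first by symbol
        assert ranking.genes[:2] == ("GENEA", "GENEB")
        assert ranking.scores[0] == ranking.scores[1]
        assert list(ranking.scores) == sorted(ranking.scores, reverse=True)

    def test_scaling_all_weights_preserves_order(self, toy_matrix, uniform_preweight):
        r1 = dg.rank_genes(toy_matrix, dg.WeightVector((1,) * 7), uniform_preweight)
        r3 = dg.rank_genes(toy_matrix, dg.WeightVector((3,) * 7), uniform_preweight)
        assert r1.genes == r3.genes

    def test_missing_core_gene_raises(self, toy_matrix, uniform_preweight):
        core = dg.CoreGeneSet(("GENEA", "NOTHERE"))
        with pytest.raises(ValidationError, match="absent"):
            dg.rank_genes(toy_matrix, dg.WeightVector((1,) * 7), uniform_preweight, core)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_upweighting_a_genes_only_source_never_worsens_its_rank(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        scores = np.where(rng.random((n, 7)) < 0.4, rng.uniform(0, 5, (n, 7)), 0.0)
        source = int(rng.integers(7))
        scores[0] = 0.0
        scores[0, source] = rng.uniform(0.5, 5.0)
        matrix = dg.EvidenceMatrix(tuple(f"G{i:02d}" for i in range(n)), scores)
        pre = dg.PreWeightVector.uniform()
        base = np.asarray([1, 1, 1, 1, 1, 1, 1])
        prev_rank = None
        for wi in range(1, 9):
            w = base.copy()
            w[source] = wi
            rank = dg.rank_genes(matrix, dg.WeightVector(tuple(w)), pre).position_of("G00")
            if prev_rank is not None:
                assert rank <= prev_rank
            prev_rank = rank


class TestCorePositions:
    def _ranking(self, n=10):
        genes = tuple(f"G{i:02d}" for i in range(n))
        return dg.RankedGeneList(genes, tuple(float(n - i) for i in range(n)))

    def test_phi_090_with_three_core_genes(self):
        ranking = self._ranking()
        core = dg.CoreGeneSet(("G01", "G04", "G08"))  # ranks 2, 5, 9
        assert dg.core_gene_positions(ranking, core, 0.9) == (9, 9)

    def test_phi_060_picks_second_core_gene(self):
        ranking = self._ranking()
        core = dg.CoreGeneSet(("G01", "G04", "G08"))
        assert dg.core_gene_positions(ranking, core, 0.6) == (5, 9)

    def test_all_core_genes_on_top(self):
        ranking = self._ranking()
        core = dg.CoreGeneSet(("G00", "G01", "G02", "G03"))
        m = math.ceil(0.75 * 4)
        assert dg.core_gene_positions(ranking, core, 0.75) == (m, 4)

    def test_j_never_exceeds_l_and_phi_one_collapses(self):
        ranking = self._ranking()
        core = dg.CoreGeneSet(("G03", "G06", "G09"))
        for phi in (0.1, 0.4, 0.7, 1.0):
            j, l = dg.core_gene_positions(ranking, core, phi)
            assert j <= l
        assert dg.core_gene_positions(ranking, core, 1.0)[0] == 10


def naive_select(matrix, core, pre, phi, eta, grid):
    """Reference implementation: materialize every ranking with plain sorts."""
    out = []
    threshold = math.ceil(eta * len(matrix))
    m = math.ceil(phi * len(core))
    for w in grid:
        combined = {
            g: dg.combined_score(matrix.score_vector(g), w, pre) for g in matrix.genes
        }
        ordered = sorted(matrix.genes, key=lambda g: (-combined[g], g))
        positions = sorted(ordered.index(g) + 1 for g in core.genes)
        out.append((w.values, positions[m - 1], positions[-1], positions[m - 1] <= threshold))
    return out


class TestSelectMatrices:
    def test_threshold_arithmetic_pass_and_fail(self, toy_matrix, uniform_preweight):
        core = dg.CoreGeneSet(("GENEA", "GENEB"))
        grid = [dg.WeightVector((1,) * 7)]
        (res_pass,) = dg.select_matrices(
            toy_matrix, core, uniform_preweight, 1.0, 0.5, grid
        )
        assert res_pass.passed and (res_pass.position_j, res_pass.position_l) == (2, 2)
        (res_fail,) = dg.select_matrices(
            toy_matrix, core, uniform_preweight, 1.0, 0.2, grid
        )
        assert not res_fail.passed  # threshold ceil(0.2*5)=1 < j=2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_naive_reference_on_exhaustive_small_grid(
        self, seed, uniform_preweight
    ):
        rng = np.random.default_rng(seed)
        n = 15
        scores = np.where(rng.random((n, 7)) < 0.5, rng.uniform(0, 5, (n, 7)), 0.0)
        # inject exact score ties to exercise the symbol tie-break
        scores[3] = scores[8]
        matrix = dg.EvidenceMatrix(tuple(f"G{i:02d}" for i in range(n)), scores)
        core = dg.CoreGeneSet(tuple(rng.choice(matrix.genes, 4, replace=False)))
        grid = list(dg.enumerate_weight_vectors(7, 2))  # 128 vectors, exhaustive
        fast = dg.select_matrices(
            matrix, core, uniform_preweight, 0.75, 0.3, grid, chunk_size=17
        )
        slow = naive_select(matrix, core, uniform_preweight, 0.75, 0.3, grid)
        assert [
            (r.weights.values, r.position_j, r.position_l, r.passed) for r in fast
        ] == slow

    def test_hard_criteria_post_filter(self, toy_matrix, uniform_preweight):
        core = dg.CoreGeneSet(("GENEA", "GENEC"))
        grid = [dg.WeightVector((1,) * 7)]
        results = dg.select_matrices(toy_matrix, core, uniform_preweight, 1.0, 0.9, grid)
        assert dg.apply_hard_criteria(results, max_j=5, max_l=5)
        assert not dg.apply_hard_criteria(results, max_j=1)

    def test_eta_bounds(self, toy_matrix, uniform_preweight):
        core = dg.CoreGeneSet(("GENEA", "GENEB"))
        with pytest.raises(ValidationError):
            dg.select_matrices(
                toy_matrix, core, uniform_preweight, 0.9, 1.0, [dg.WeightVector((1,) * 7)]
            )
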