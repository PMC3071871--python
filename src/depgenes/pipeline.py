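"""End-to-end orchestration: grid scan -> GWA evaluation -> cutoff selection.

:func:`run_prioritization` is the programmatic equivalent of the full
published procedure: enumerate the weight grid, keep matrices that
concentrate the core genes at the top of the ranking, evaluate the
survivors against the GWA data by random-set comparison, pick the optimal
matrix, and cut the final prioritized gene list at a score cutoff (supplied
or suggested from the core/candidate score separation).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import NoMatrixPassedError, ValidationError
from .evidence import (
    N_SOURCES,
    CoreGeneSet,
    DepGeneTable,
    EvidenceMatrix,
    PreWeightVector,
)
from .gwa import EvaluationSummary, GwaGeneTable, evaluate_prioritized_set
from .prioritize import (
    MatrixSelectionResult,
    RankedGeneList,
    WeightVector,
    apply_hard_criteria,
    enumerate_weight_vectors,
    rank_genes,
    select_matrices,
)
from .selection import (
    CutoffDiagnostics,
    choose_cutoff,
    select_depgenes,
    suggest_cutoff,
)


@dataclass(frozen=True)
class PrioritizationRun:
    """Everything one pipeline run produced."""

    selection: tuple[MatrixSelectionResult, ...]          # full grid scan
    evaluated: tuple[tuple[MatrixSelectionResult, EvaluationSummary], ...]
    optimal: MatrixSelectionResult
    optimal_summary: EvaluationSummary
    ranking: RankedGeneList                               # under the optimal matrix
    cutoff: float
    cutoff_diagnostics: tuple[CutoffDiagnostics, ...]
    depgenes: DepGeneTable

    @property
    def optimal_weights(self) -> WeightVector:
        return self.optimal.weights


def pick_optimal(
    evaluated: Sequence[tuple[MatrixSelectionResult, EvaluationSummary]],
) -> tuple[MatrixSelectionResult, EvaluationSummary]:
    """Highest evaluation mean; ties to smaller j, then smaller l, then the
    lexicographically smallest weight vector (fixed for determinism)."""
    if not evaluated:
        raise ValidationError("no evaluated matrices to pick from")
    return min(
        evaluated,
        key=lambda re: (
            -re[1].mean,
            re[0].position_j,
            re[0].position_l,
            re[0].weights.values,
        ),
    )


def run_prioritization(
    evidence: EvidenceMatrix,
    core: CoreGeneSet,
    preweight: PreWeightVector,
    gwa: GwaGeneTable,
    phi: float = 0.9,
    eta: float = 0.05,
    d: int = 4,
    n_random: int = 1000,
    repeats: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
    cutoff: float | None = None,
    max_evaluate: int = 50,
    max_j: int | None = None,
    max_l: int | None = None,
    chunk_size: int = 1024,
) -> PrioritizationRun:
    """Run the full prioritization pipeline.

    Parameters follow the underlying operations; notable orchestration
    choices:

    * survivors of the core-gene stage (optionally post-filtered by the
      hard criteria ``max_j`` / ``max_l``) are ordered by concentration
      (j, then l, then weights) and at most ``max_evaluate`` of them are
      evaluated against the GWA data — the grid can pass many matrices and
      the evaluation is the expensive stage;
    * every matrix is evaluated with the same seed, i.e. against common
      random gene sets, so the mean-based comparison between matrices is
      paired rather than noise-dominated;
    * ``cutoff=None`` selects the cutoff maximizing the separation between
      core-gene and candidate score distributions under the optimal matrix.

    Raises :class:`NoMatrixPassedError` (with near-misses) when the grid
    yields no qualifying matrix.
    """
    grid = enumerate_weight_vectors(N_SOURCES, d)
    selection = select_matrices(
        evidence, core, preweight, phi, eta, grid, chunk_size=chunk_size
    )
    survivors = apply_hard_criteria(selection, max_j=max_j, max_l=max_l)
    if not survivors:
        near = sorted(selection, key=lambda r: (r.position_j, r.position_l))[:5]
        raise NoMatrixPassedError(
            f"none of {len(selection)} weight matrices passed the core-gene "
            f"criterion (phi={phi}, eta={eta}); best j values: "
            f"{[r.position_j for r in near]}",
            near_misses=near,
        )
    survivors.sort(key=lambda r: (r.position_j, r.position_l, r.weights.values))
    to_evaluate = survivors[:max_evaluate]

    evaluated = []
    for result in to_evaluate:
        ranking = rank_genes(evidence, result.weights, preweight, core)
        summary = evaluate_prioritized_set(
            ranking,
            gwa,
            j=result.position_j,
            n_random=n_random,
            repeats=repeats,
            alpha=alpha,
            seed=seed,
        )
        evaluated.append((result, summary))

    optimal, optimal_summary = pick_optimal(evaluated)
    ranking = rank_genes(evidence, optimal.weights, preweight, core)
    scores = dict(zip(ranking.genes, ranking.scores))
    core_scores = [scores[g] for g in core.genes]
    diagnostics = tuple(suggest_cutoff(core_scores, list(scores.values())))
    final_cutoff = choose_cutoff(diagnostics) if cutoff is None else float(cutoff)
    depgenes = select_depgenes(scores, final_cutoff)

    return PrioritizationRun(
        selection=tuple(selection),
        evaluated=tuple(evaluated),
        optimal=optimal,
        optimal_summary=optimal_summary,
        ranking=ranking,
        cutoff=final_cutoff,
        cutoff_diagnostics=diagnostics,
        depgenes=depgenes,
    )
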