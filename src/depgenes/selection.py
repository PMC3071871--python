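"""Cutoff-based final gene selection and robustness diagnostics.

The prioritized list ("DEPgenes" in the depression application) is the set
of genes whose combined score reaches a cutoff chosen where the score
distributions of the core genes and of the bulk candidates separate
cleanly.  Robustness checks: Spearman correlation of the rankings induced
by alternative weight matrices, and overlap of the lists selected under
alternative core gene sets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .evidence import CoreGeneSet, DepGeneTable, EvidenceMatrix, PreWeightVector
from .prioritize import (
    MatrixSelectionResult,
    WeightVector,
    rank_genes,
    select_matrices,
)


@dataclass(frozen=True)
class CutoffDiagnostics:
    """Separation achieved by one candidate cutoff.

    ``separation`` is the Youden-style difference between the fraction of
    core genes and the fraction of all candidates scoring at or above the
    cutoff.
    """

    cutoff: float
    core_fraction: float
    candidate_fraction: float
    separation: float

    def __post_init__(self):
        for f in (self.core_fraction, self.candidate_fraction):
            if not (0 <= f <= 1):
                raise ValidationError("fractions must lie in [0, 1]")


def select_depgenes(scores: Mapping[str, float], cutoff: float) -> DepGeneTable:
    """Genes with combined score >= cutoff, sorted descending (ties by symbol)."""
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    kept = [(str(g).upper(), float(s)) for g, s in scores.items() if s >= cutoff]
    kept.sort(key=lambda gs: (-gs[1], gs[0]))
    return DepGeneTable(tuple(g for g, _ in kept), tuple(s for _, s in kept))


def suggest_cutoff(
    core_scores: Sequence[float],
    all_scores: Sequence[float],
    grid: Sequence[float] | None = None,
) -> list[CutoffDiagnostics]:
    """Scan candidate cutoffs and report core/candidate separation at each.

    ``grid`` defaults to the distinct observed scores.  The suggested cutoff
    (see :func:`choose_cutoff`) maximizes the separation; ties go to the
    smallest cutoff.
    """
    core = np.asarray(core_scores, dtype=float)
    allv = np.asarray(all_scores, dtype=float)
    if core.size == 0 or allv.size == 0:
        raise ValidationError("score sets must be non-empty")
    if grid is None:
        grid = np.unique(np.concatenate([core, allv]))
    out = []
    for c in grid:
        cf = float((core >= c).mean())
        af = float((allv >= c).mean())
        out.append(CutoffDiagnostics(float(c), cf, af, cf - af))
    return out


def choose_cutoff(diagnostics: Sequence[CutoffDiagnostics]) -> float:
    """Cutoff with maximal separation; ties resolved to the smallest cutoff."""
    if not diagnostics:
        raise ValidationError("no cutoff diagnostics to choose from")
    best = max(diagnostics, key=lambda d: (d.separation, -d.cutoff))
    return best.cutoff


def rank_correlation(
    matrices: Sequence[WeightVector],
    evidence: EvidenceMatrix,
    preweight: PreWeightVector,
) -> tuple[np.ndarray, float]:
    """Pairwise Spearman correlation of the rankings induced by weight matrices.

    Returns the full correlation matrix (mid-ranks for ties) and the mean
    over off-diagonal pairs.  At the published scale ten retained matrices
    gave a mean of 0.92.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least 2 weight matrices to correlate")
    pre = preweight.as_array()
    cols = np.stack(
        [evidence.scores @ (pre * w.as_array()) for w in matrices], axis=1
    )
    # Spearman with mid-ranks = Pearson correlation of the rank transforms
    ranks = np.apply_along_axis(rankdata, 0, cols)
    rho = np.corrcoef(ranks, rowvar=False)
    off = rho[~np.eye(len(matrices), dtype=bool)]
    return rho, float(off.mean())


@dataclass(frozen=True)
class CoreSetComparison:
    """Selection outcome under two alternative core gene sets."""

    best_matrix_a: WeightVector
    best_matrix_b: WeightVector
    depgenes_a: DepGeneTable
    depgenes_b: DepGeneTable
    overlap: tuple[str, ...]
    mean_score_b_only: float  # mean combined score, under matrix A, of genes only B selected


def best_matrix_by_core(results: Iterable[MatrixSelectionResult]) -> MatrixSelectionResult:
    """Best passing matrix by core-gene concentration: smallest (j, l), then
    lexicographically smallest weights."""
    passing = [r for r in results if r.passed]
    if not passing:
        raise ValidationError("no weight matrix passed the core-gene criterion")
    return min(passing, key=lambda r: (r.position_j, r.position_l, r.weights.values))


def compare_core_sets(
    evidence: EvidenceMatrix,
    preweight: PreWeightVector,
    grid: Sequence[WeightVector],
    core_a: CoreGeneSet,
    core_b: CoreGeneSet,
    phi: float,
    eta: float,
    cutoff: float,
) -> CoreSetComparison:
    """Run the matrix selection + cutoff selection under each core set.

    Each core set gets its own grid scan; the best passing matrix (by core
    concentration) defines that core set's combined scores and selected
    list.  The report includes the intersection of the two lists and the
    mean combined score — under core A's matrix — of the genes selected
    only under core B (low values mean B's extra genes were never close
    under A, i.e. the disagreement is mild).
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("weight grid must be non-empty")

    def run(core: CoreGeneSet):
        results = select_matrices(evidence, core, preweight, phi, eta, grid)
        best = best_matrix_by_core(results)
        ranking = rank_genes(evidence, best.weights, preweight, core)
        scores = dict(zip(ranking.genes, ranking.scores))
        return best.weights, scores, select_depgenes(scores, cutoff)

    w_a, scores_a, dep_a = run(core_a)
    w_b, _, dep_b = run(core_b)
    overlap = tuple(sorted(set(dep_a.genes) & set(dep_b.genes)))
    b_only = sorted(set(dep_b.genes) - set(dep_a.genes))
    mean_b_only = float(np.mean([scores_a[g] for g in b_only])) if b_only else math.nan
    return CoreSetComparison(w_a, w_b, dep_a, dep_b, overlap, mean_b_only)
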