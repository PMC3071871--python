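"""Combined scores, weight-grid enumeration and core-gene matrix selection.

A candidate weight matrix assigns an integer weight ``W_i`` in ``1..d`` to
each of the seven data sources; the grid holds all ``d^N`` assignments
(``8^7 = 2,097,152`` at the published scale).  For one weight vector the
combined score of a gene is ``sum_i preWeight_i * S_i * W_i`` and all genes
are ranked by it, descending.  A matrix is retained when it concentrates the
core genes near the top of that ranking: the rank ``j`` of the
``ceil(phi*K)``-th core gene must fall within the top ``ceil(eta * N)``
candidates.  The rank ``l`` of the last core gene is carried along for hard
post-filters.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ValidationError
from .evidence import N_SOURCES, CoreGeneSet, EvidenceMatrix, PreWeightVector

#: The published optimal weight matrix, in canonical source order.
OPTIMAL_WEIGHT_MATRIX: tuple[int, ...] = (2, 1, 1, 8, 1, 1, 7)


@dataclass(frozen=True)
class WeightVector:
    """Integer weights, one per source, each >= 1."""

    values: tuple[int, ...]

    def __post_init__(self):
        vals = tuple(int(v) for v in self.values)
        if len(vals) == 0:
            raise ValidationError("weight vector must be non-empty")
        if any(v < 1 for v in vals):
            raise ValidationError(f"weights must be >= 1: {vals}")
        object.__setattr__(self, "values", vals)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __str__(self) -> str:
        return "[" + ",".join(str(v) for v in self.values) + "]"


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by combined score, descending; ties by ascending symbol."""

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def position_of(self, gene: str) -> int:
        """1-based rank of a gene."""
        try:
            return self.genes.index(gene.upper()) + 1
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in ranked list") from None

    def top(self, k: int) -> tuple[str, ...]:
        return self.genes[:k]


@dataclass(frozen=True)
class MatrixSelectionResult:
    """Core-gene concentration of one weight matrix."""

    weights: WeightVector
    position_j: int
    position_l: int
    passed: bool

    def __post_init__(self):
        if self.position_j > self.position_l:
            raise ValidationError("position j cannot exceed position l")


def combined_score(
    scores: Sequence[float], weights: WeightVector, preweight: PreWeightVector
) -> float:
    """``sum_i preWeight_i * S_i * W_i`` for one gene."""
    s = np.asarray(scores, dtype=float)
    w = weights.as_array()
    p = preweight.as_array()
    if not (len(s) == len(w) == len(p)):
        raise ValidationError(
            f"length mismatch: scores {len(s)}, weights {len(w)}, preweight {len(p)}"
        )
    return float(np.sum(p * s * w))


def effective_weights(weights: WeightVector, preweight: PreWeightVector) -> tuple[float, ...]:
    """Per-source multipliers ``preWeight_i * W_i`` (e.g. (3, 1, 1.5, 4, 1, 1, 3.5))."""
    return tuple(float(p * w) for p, w in zip(preweight.values, weights.values))


def enumerate_weight_vectors(n_sources: int = N_SOURCES, d: int = 8) -> Iterator[WeightVector]:
    """Yield all ``d ** n_sources`` weight vectors over {1..d}, lexicographically.

    Streaming: the grid is never materialized, so the full published pool
    (8^7 vectors) can be scanned in bounded memory.
    """
    if n_sources < 1 or d < 1:
        raise ValidationError("need n_sources >= 1 and d >= 1")
    for values in itertools.product(range(1, d + 1), repeat=n_sources):
        yield WeightVector(values)


def _order_keys(matrix: EvidenceMatrix) -> np.ndarray:
    """Index of each gene in ascending-symbol order (tie-break key)."""
    order = np.argsort(np.asarray(matrix.genes))
    keys = np.empty(len(matrix), dtype=np.int64)
    keys[order] = np.arange(len(matrix))
    return keys


def rank_genes(
    matrix: EvidenceMatrix,
    weights: WeightVector,
    preweight: PreWeightVector,
    core: CoreGeneSet | None = None,
) -> RankedGeneList:
    """Rank all genes by combined score (descending; ties by ascending symbol).

    Candidate genes and core genes are sorted together in one merged list;
    core genes must already be rows of the evidence matrix (the published
    core genes are drawn from the reviewed candidates) and are not
    double-counted.
    """
    if core is not None:
        missing = [g for g in core.genes if g not in matrix.gene_index]
        if missing:
            raise ValidationError(f"core genes absent from evidence matrix: {missing}")
    w = weights.as_array()
    p = preweight.as_array()
    if len(w) != matrix.scores.shape[1] or len(p) != matrix.scores.shape[1]:
        raise ValidationError("weight/preweight length does not match source count")
    combined = matrix.scores @ (p * w)
    keys = _order_keys(matrix)
    order = np.lexsort((keys, -combined))
    genes = tuple(matrix.genes[i] for i in order)
    return RankedGeneList(genes, tuple(float(combined[i]) for i in order))


def phi_th_index(n_core: int, phi: float) -> int:
    """Which core gene (1-based, counted from the top) defines position j."""
    if not (0 < phi <= 1):
        raise ValidationError(f"phi must be in (0, 1], got {phi}")
    return math.ceil(phi * n_core)


def core_gene_positions(
    ranking: RankedGeneList, core: CoreGeneSet, phi: float
) -> tuple[int, int]:
    """Ranks (j, l) of the ``ceil(phi*K)``-th and the last core gene."""
    m = phi_th_index(len(core), phi)
    positions = sorted(ranking.position_of(g) for g in core.genes)
    return positions[m - 1], positions[-1]


def select_matrices(
    matrix: EvidenceMatrix,
    core: CoreGeneSet,
    preweight: PreWeightVector,
    phi: float,
    eta: float,
    grid: Iterable[WeightVector],
    chunk_size: int = 1024,
) -> list[MatrixSelectionResult]:
    """Evaluate every weight vector of ``grid`` against the core-gene criterion.

    A matrix passes when position ``j`` (rank of the ``ceil(phi*K)``-th core
    gene) is at most ``ceil(eta * N_candidates)``.  Vectorized in chunks so
    arbitrarily large grids run in bounded memory.
    """
    if not (0 < eta < 1):
        raise ValidationError(f"eta must be in (0, 1), got {eta}")
    missing = [g for g in core.genes if g not in matrix.gene_index]
    if missing:
        raise ValidationError(f"core genes absent from evidence matrix: {missing}")
    m = phi_th_index(len(core), phi)
    threshold = math.ceil(eta * len(matrix))

    pre_scores = matrix.scores * preweight.as_array()  # (n_genes, 7)
    keys = _order_keys(matrix)
    core_idx = np.asarray([matrix.gene_index[g] for g in core.genes])
    # symbol-order tie-break masks, one row per core gene
    tie_before = keys[None, :] < keys[core_idx, None]  # (K, n_genes)

    results: list[MatrixSelectionResult] = []
    it = iter(grid)
    while True:
        chunk = list(itertools.islice(it, chunk_size))
        if not chunk:
            break
        wmat = np.stack([wv.as_array() for wv in chunk])  # (B, 7)
        combined = pre_scores @ wmat.T                     # (n_genes, B)
        core_scores = combined[core_idx]                   # (K, B)
        ranks = np.empty_like(core_scores, dtype=np.int64)
        for k in range(len(core_idx)):
            higher = combined > core_scores[k]
            tied = (combined == core_scores[k]) & tie_before[k][:, None]
            ranks[k] = 1 + higher.sum(axis=0) + tied.sum(axis=0)
        ranks.sort(axis=0)
        js, ls = ranks[m - 1], ranks[-1]
        for wv, j, l in zip(chunk, js, ls):
            results.append(
                MatrixSelectionResult(wv, int(j), int(l), bool(j <= threshold))
            )
    return results


def apply_hard_criteria(
    results: Iterable[MatrixSelectionResult],
    max_j: int | None = None,
    max_l: int | None = None,
) -> list[MatrixSelectionResult]:
    """Post-filter passing matrices by fixed rank thresholds on j and l.

    The published run used j <= 160 and l <= 1200 on a 5,055-gene universe;
    the thresholds are data-scale-specific, hence configurable.
    """
    out = []
    for r in results:
        if not r.passed:
            continue
        if max_j is not None and r.position_j > max_j:
            continue
        if max_l is not None and r.position_l > max_l:
            continue
        out.append(r)
    return out
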