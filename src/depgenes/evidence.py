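"""Data model and file I/O for evidence matrices, core genes and fixtures.

The central container is :class:`EvidenceMatrix`: a genes x 7 table of
non-negative per-source evidence scores ``S_i``.  The seven data sources are
fixed and ordered; every weight vector and pre-weight vector in the package
uses the same order, so position ``i`` always refers to the same source:

``association, linkage, expression_human, literature_human, pathway,
expression_animal, literature_animal``

Bundled fixtures: the published 169-gene prioritized list with combined
scores, the 14-gene core set, and the default per-source pre-weights.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: Canonical source order; weight vectors and pre-weights follow it.
SOURCES: tuple[str, ...] = (
    "association",
    "linkage",
    "expression_human",
    "literature_human",
    "pathway",
    "expression_animal",
    "literature_animal",
)

N_SOURCES = len(SOURCES)


def _data_path(name: str):
    return resources.files("depgenes.data").joinpath(name)


@dataclass(frozen=True)
class EvidenceMatrix:
    """Genes x sources table of per-source evidence scores.

    Parameters
    ----------
    genes
        Unique, upper-case gene identifiers (row labels).
    scores
        Array of shape ``(len(genes), 7)``; finite, non-negative.  A zero
        means "no evidence from this source".
    sources
        Source labels in canonical order; defaults to :data:`SOURCES`.
    """

    genes: tuple[str, ...]
    scores: np.ndarray
    sources: tuple[str, ...] = SOURCES

    def __post_init__(self):
        genes = tuple(str(g).upper() for g in self.genes)
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape != (len(genes), len(self.sources)):
            raise ValidationError(
                f"scores shape {scores.shape} does not match "
                f"{len(genes)} genes x {len(self.sources)} sources"
            )
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("evidence scores must be finite")
        if np.any(scores < 0):
            raise ValidationError("evidence scores must be non-negative")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "sources", tuple(self.sources))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def score_vector(self, gene: str) -> np.ndarray:
        """Return the 7-score row for one gene."""
        try:
            return self.scores[self.gene_index[gene.upper()]]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in evidence matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.genes), columns=list(self.sources))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EvidenceMatrix":
        missing = [s for s in SOURCES if s not in frame.columns]
        if missing:
            raise FormatError(f"missing source columns: {missing}")
        return cls(tuple(frame.index), frame[list(SOURCES)].to_numpy(dtype=float))


@dataclass(frozen=True)
class PreWeightVector:
    """Fixed per-source pre-multipliers in [0.5, 1.5].

    Pre-weights compensate for the unequal raw score ranges of the seven
    sources before the integer weight grid is applied; the combined score of
    a gene is ``sum_i pre_i * S_i * W_i``.
    """

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) != N_SOURCES:
            raise ValidationError(f"preWeight must have {N_SOURCES} entries, got {len(vals)}")
        if any(not (0.5 <= v <= 1.5) for v in vals):
            raise ValidationError(f"preWeight values must lie in [0.5, 1.5]: {vals}")
        object.__setattr__(self, "values", vals)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def uniform(cls) -> "PreWeightVector":
        """All-ones pre-weights (the robustness-check variant)."""
        return cls((1.0,) * N_SOURCES)


@dataclass(frozen=True)
class CoreGeneSet:
    """A small set of well-supported disease genes used as positives."""

    genes: tuple[str, ...]

    def __post_init__(self):
        genes = tuple(str(g).upper() for g in self.genes)
        if len(set(genes)) != len(genes):
            raise ValidationError("core gene set contains duplicates")
        if len(genes) < 2:
            raise ValidationError("core gene set needs at least 2 genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


@dataclass(frozen=True)
class DepGeneTable:
    """Final prioritized gene list: (gene, combined score) rows, scores > 0."""

    genes: tuple[str, ...]
    combined_scores: tuple[float, ...]

    def __post_init__(self):
        genes = tuple(str(g).upper() for g in self.genes)
        scores = tuple(float(s) for s in self.combined_scores)
        if len(genes) != len(scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate genes in prioritized table")
        if any(s <= 0 for s in scores):
            raise ValidationError("combined scores must be strictly positive")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "combined_scores", scores)

    def __len__(self) -> int:
        return len(self.genes)

    def score_of(self, gene: str) -> float:
        try:
            return self.combined_scores[self.genes.index(gene.upper())]
        except ValueError:
            raise KeyError(gene) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.genes), "combined_score": list(self.combined_scores)}
        )


@dataclass(frozen=True)
class GeneCoordinates:
    """Genomic interval of one gene, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chromosome label must be non-empty")
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: start {self.start} > end {self.end}")
        object.__setattr__(self, "gene", str(self.gene).upper())


# ---------------------------------------------------------------------------
# readers / writers


def read_evidence_table(path, source_names: Sequence[str] = SOURCES) -> EvidenceMatrix:
    """Read a tab-separated evidence table.

    Expected header: ``gene`` followed by the seven source columns in
    canonical order.  Empty cells mean "no evidence" and become 0.  Rows that
    repeat a gene with identical scores collapse to one; conflicting
    duplicates are an error.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    expected = ["gene", *source_names]
    if list(frame.columns) != expected:
        raise FormatError(
            f"evidence table header {list(frame.columns)} != expected {expected}"
        )
    frame["gene"] = frame["gene"].str.upper()
    frame[list(source_names)] = frame[list(source_names)].fillna(0.0)
    if (frame[list(source_names)].to_numpy() < 0).any():
        raise ValidationError(f"negative score in evidence table {path}")
    deduped = frame.drop_duplicates()
    if deduped["gene"].duplicated().any():
        bad = sorted(deduped.loc[deduped["gene"].duplicated(), "gene"].unique())
        raise ValidationError(f"conflicting duplicate rows for genes {bad[:5]}")
    deduped = deduped.set_index("gene")
    return EvidenceMatrix.from_frame(deduped)


def write_evidence_table(matrix: EvidenceMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_core_genes(path) -> CoreGeneSet:
    """Read a core gene list: one symbol per line, ``#`` comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return CoreGeneSet(tuple(genes))


def read_preweight(path) -> PreWeightVector:
    """Read a pre-weight YAML file keyed by source name."""
    data = yaml.safe_load(Path(path).read_text())
    mapping = data["preweight"] if "preweight" in data else data
    try:
        return PreWeightVector(tuple(float(mapping[s]) for s in SOURCES))
    except KeyError as exc:
        raise FormatError(f"preweight file {path} missing source {exc}") from None


def read_gene_coordinates(path) -> list[GeneCoordinates]:
    """Read gene coordinates from TSV ``(chrom, start, end, gene)``.

    A plain ``.tsv`` file is taken as 1-based inclusive; a ``.bed`` file is
    converted from 0-based half-open coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str},
    )
    bed = path.suffix.lower() == ".bed"
    out = []
    for row in frame.itertuples(index=False):
        start = int(row.start) + 1 if bed else int(row.start)
        out.append(GeneCoordinates(gene=row.gene, chrom=row.chrom, start=start, end=int(row.end)))
    return out


# ---------------------------------------------------------------------------
# bundled fixtures


def load_fixture_depgenes() -> DepGeneTable:
    """The published 169-gene prioritized list with combined scores >= 15."""
    with resources.as_file(_data_path("depgenes_table2.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    return DepGeneTable(tuple(frame["gene"]), tuple(frame["combined_score"]))


def load_fixture_core_genes() -> CoreGeneSet:
    """The 14-gene expert-curated core set."""
    with resources.as_file(_data_path("core_genes.txt")) as p:
        return read_core_genes(p)


def load_default_preweight() -> PreWeightVector:
    """Default pre-weights (1.5, 1, 1.5, 0.5, 1, 1, 0.5) in source order."""
    with resources.as_file(_data_path("preweight.yaml")) as p:
        return read_preweight(p)
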