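"""Per-source scoring: raw evidence -> the score S_i used in prioritization.

Each of the seven data sources carries a different kind of raw evidence and
its own scoring rule:

* association — count of genetic association studies and the proportion
  reporting a positive association, banded through a two-criteria lookup
  table (0..4).  Banding, rather than the studies' own p-values, damps the
  inflation of positive proportions caused by publication bias.
* linkage — max(LOD, -log10 p) over linkage peaks covering the gene; scores
  below 1 are floored to 0 (range 0–4.6 in the published data).
* expression (human / animal) — -log10 p for genes passing a p < 0.05
  differential-expression filter, 0 otherwise (ranges 0–4.6 and 0–5.6).
* literature (human / animal) — number of distinct disease keywords (out of
  a fixed six-word vocabulary) co-occurring with the gene in citations
  (range 0–6 human, observed 0–4 animal).
* pathway — membership tier: 3 for monoamine-deficiency pathways, 2 for
  HPA-axis, 1 for other disease mechanisms; max over memberships.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import math

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .evidence import SOURCES, EvidenceMatrix

EXPRESSION_P_CUTOFF = 0.05

#: Human disease keywords used for literature hits.
HUMAN_KEYWORDS: frozenset[str] = frozenset({
    "depression",
    "depressive disorder",
    "unipolar disorder",
    "dysthymia",
    "major depression",
    "major depressive disorder",
})

#: Animal-model behavioural paradigms used for literature hits.
ANIMAL_KEYWORDS: frozenset[str] = frozenset({
    "forced swim test",
    "tail suspension test",
    "elevate plus maze",
    "novelty induced hypophagia",
    "olfactory bulbectomy",
    "open field test",
})

PATHWAY_TIERS: dict[str, int] = {"monoamine": 3, "hpa_axis": 2, "other": 1}


# ---------------------------------------------------------------------------
# evidence records


@dataclass(frozen=True)
class AssociationEvidence:
    n_studies: int
    n_positive: int

    def __post_init__(self):
        if self.n_studies < 0 or self.n_positive < 0:
            raise ValidationError("study counts must be non-negative")
        if self.n_positive > self.n_studies:
            raise ValidationError(
                f"n_positive {self.n_positive} exceeds n_studies {self.n_studies}"
            )


@dataclass(frozen=True)
class LinkageEvidence:
    lod: Optional[float] = None
    neglog10p: Optional[float] = None

    def __post_init__(self):
        if self.lod is None and self.neglog10p is None:
            raise ValidationError("linkage evidence needs a LOD score or a -log10 p")
        for v in (self.lod, self.neglog10p):
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"linkage statistic must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ExpressionEvidence:
    p_value: float

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"expression p-value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class LiteratureEvidence:
    keywords_hit: frozenset[str]
    vocabulary: frozenset[str] = HUMAN_KEYWORDS

    def __post_init__(self):
        hits = frozenset(k.lower() for k in self.keywords_hit)
        vocab = frozenset(k.lower() for k in self.vocabulary)
        if not hits <= vocab:
            raise ValidationError(f"keywords outside vocabulary: {sorted(hits - vocab)}")
        object.__setattr__(self, "keywords_hit", hits)
        object.__setattr__(self, "vocabulary", vocab)


@dataclass(frozen=True)
class PathwayEvidence:
    mechanisms: frozenset[str]

    def __post_init__(self):
        mechs = frozenset(m.lower() for m in self.mechanisms)
        unknown = mechs - PATHWAY_TIERS.keys()
        if unknown:
            raise ValidationError(f"unknown pathway mechanisms: {sorted(unknown)}")
        object.__setattr__(self, "mechanisms", mechs)


# ---------------------------------------------------------------------------
# association scoring table


@dataclass(frozen=True)
class AssociationScoringTable:
    """Two-criteria lookup (study-count band x positive-proportion band).

    ``study_bands`` / ``proportion_bands`` are the interior lower band edges;
    ``scores[i][j]`` is the score for the i-th study band and j-th
    proportion band.  The matrix must be monotone non-decreasing along both
    axes so that more studies (at fixed proportion) or a higher positive
    proportion (at fixed count) can never lower the score.
    """

    study_bands: tuple[int, ...]
    proportion_bands: tuple[float, ...]
    scores: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        mat = np.asarray(self.scores, dtype=int)
        if mat.shape != (len(self.study_bands) + 1, len(self.proportion_bands) + 1):
            raise ConfigurationError(
                f"score matrix shape {mat.shape} inconsistent with band counts"
            )
        if np.any(mat < 0) or np.any(mat > 4):
            raise ConfigurationError("association scores must lie in 0..4")
        if np.any(np.diff(mat, axis=0) < 0) or np.any(np.diff(mat, axis=1) < 0):
            raise ConfigurationError("association scoring table must be monotone in both criteria")

    def lookup(self, n_studies: int, proportion: float) -> int:
        i = int(np.searchsorted(self.study_bands, n_studies, side="right"))
        j = int(np.searchsorted(self.proportion_bands, proportion, side="right"))
        return int(self.scores[i][j])

    @classmethod
    def from_yaml(cls, path) -> "AssociationScoringTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            tuple(int(b) for b in data["study_bands"]),
            tuple(float(b) for b in data["proportion_bands"]),
            tuple(tuple(int(s) for s in row) for row in data["scores"]),
        )

    @classmethod
    def default(cls) -> "AssociationScoringTable":
        with resources.as_file(
            resources.files("depgenes.data").joinpath("association_scoring.yaml")
        ) as p:
            return cls.from_yaml(p)


# ---------------------------------------------------------------------------
# scorers


def score_association(
    ev: AssociationEvidence, table: AssociationScoringTable | None = None
) -> int:
    """Score 0..4 from study count and positive proportion."""
    if table is None:
        table = AssociationScoringTable.default()
    if ev.n_studies == 0:
        return 0
    return table.lookup(ev.n_studies, ev.n_positive / ev.n_studies)


def score_linkage(ev: LinkageEvidence) -> float:
    """max(LOD, -log10 p), floored to 0 below 1."""
    v = max(x for x in (ev.lod, ev.neglog10p) if x is not None)
    return float(v) if v >= 1 else 0.0


def score_expression(ev: ExpressionEvidence) -> float:
    """-log10 p for genes passing the p < 0.05 extraction filter, else 0."""
    if ev.p_value >= EXPRESSION_P_CUTOFF:
        return 0.0
    return -math.log10(ev.p_value)


def score_literature(ev: LiteratureEvidence) -> int:
    """Number of distinct vocabulary keywords hit (0..6)."""
    return len(ev.keywords_hit)


def score_pathway(ev: PathwayEvidence) -> int:
    """Strongest mechanism tier: monoamine 3 > HPA axis 2 > other 1; 0 if none."""
    if not ev.mechanisms:
        return 0
    return max(PATHWAY_TIERS[m] for m in ev.mechanisms)


# ---------------------------------------------------------------------------
# matrix assembly

_Evidence = object  # any of the record types above


def build_evidence_matrix(
    raw: Mapping[str, Mapping[str, _Evidence]],
    association_table: AssociationScoringTable | None = None,
) -> EvidenceMatrix:
    """Apply the per-source scorers to raw evidence and assemble the matrix.

    ``raw`` maps gene -> {source name -> evidence record}; sources with no
    record score 0.  Expression and literature scorers are applied to the
    human and animal variants alike (the inputs differ, the rule does not).
    """
    if association_table is None:
        association_table = AssociationScoringTable.default()
    scorers = {
        "association": lambda ev: score_association(ev, association_table),
        "linkage": score_linkage,
        "expression_human": score_expression,
        "literature_human": score_literature,
        "pathway": score_pathway,
        "expression_animal": score_expression,
        "literature_animal": score_literature,
    }
    genes = sorted({g.upper() for g in raw})
    scores = np.zeros((len(genes), len(SOURCES)))
    lookup = {g.upper(): ev for g, ev in raw.items()}
    for r, gene in enumerate(genes):
        per_source = lookup[gene]
        unknown = set(per_source) - set(SOURCES)
        if unknown:
            raise ValidationError(f"{gene}: unknown sources {sorted(unknown)}")
        for c, source in enumerate(SOURCES):
            ev = per_source.get(source)
            if ev is not None:
                scores[r, c] = scorers[source](ev)
    return EvidenceMatrix(tuple(genes), scores)


# ---------------------------------------------------------------------------
# raw-evidence file readers (one TSV per source)


def read_raw_evidence(directory) -> dict[str, dict[str, _Evidence]]:
    """Read per-source raw evidence TSVs from a directory.

    Recognised files: ``association.tsv`` (gene, n_studies, n_positive),
    ``linkage.tsv`` (gene, lod, neglog10p; either may be empty),
    ``expression_human.tsv`` / ``expression_animal.tsv`` (gene, p_value),
    ``literature_human.tsv`` / ``literature_animal.tsv`` (gene, keywords,
    comma-separated) and ``pathway.tsv`` (gene, mechanisms, comma-separated).
    Missing files simply contribute no evidence.
    """
    directory = Path(directory)
    raw: dict[str, dict[str, _Evidence]] = {}

    def add(gene: str, source: str, ev) -> None:
        raw.setdefault(gene.upper(), {})[source] = ev

    path = directory / "association.tsv"
    if path.exists():
        for row in pd.read_csv(path, sep="\t").itertuples(index=False):
            add(row.gene, "association",
                AssociationEvidence(int(row.n_studies), int(row.n_positive)))
    path = directory / "linkage.tsv"
    if path.exists():
        for row in pd.read_csv(path, sep="\t").itertuples(index=False):
            lod = None if pd.isna(row.lod) else float(row.lod)
            nlp = None if pd.isna(row.neglog10p) else float(row.neglog10p)
            add(row.gene, "linkage", LinkageEvidence(lod, nlp))
    for species in ("human", "animal"):
        path = directory / f"expression_{species}.tsv"
        if path.exists():
            for row in pd.read_csv(path, sep="\t").itertuples(index=False):
                add(row.gene, f"expression_{species}", ExpressionEvidence(float(row.p_value)))
        path = directory / f"literature_{species}.tsv"
        vocab = HUMAN_KEYWORDS if species == "human" else ANIMAL_KEYWORDS
        if path.exists():
            for row in pd.read_csv(path, sep="\t").itertuples(index=False):
                kws = [] if pd.isna(row.keywords) else str(row.keywords).split(",")
                hits = frozenset(k.strip() for k in kws if k.strip())
                add(row.gene, f"literature_{species}", LiteratureEvidence(hits, vocab))
    path = directory / "pathway.tsv"
    if path.exists():
        for row in pd.read_csv(path, sep="\t").itertuples(index=False):
            mechs = [] if pd.isna(row.mechanisms) else str(row.mechanisms).split(",")
            add(row.gene, "pathway",
                PathwayEvidence(frozenset(m.strip() for m in mechs if m.strip())))
    return raw
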