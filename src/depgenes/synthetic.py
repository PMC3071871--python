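"""Synthetic inputs with planted truth for end-to-end pipeline testing.

The real inputs behind this kind of prioritization study are curated
literature/association/linkage/expression/pathway tables and an
access-restricted GWA dataset.  This module emulates their statistical
structure so every stage can be exercised and checked against a known
answer:

* an evidence matrix whose background genes carry sparse scores (each
  source non-zero with probability 0.1, magnitude uniform over that
  source's published range) and whose planted "true" genes get a mean
  score uplift in a chosen subset of informative sources;
* a core gene set sampled from the planted truth;
* SNP-level GWA results where true-gene p-values are Beta(a, 1) with
  a < 1 (enriched for small values) against a Uniform(0,1) background;
* a binary tissue matrix with a designated tissue block where true genes
  are present more often.

Everything is a pure function of (config, seed); the evidence, GWA and
tissue generators use decoupled sub-streams of the root seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .errors import ValidationError
from .evidence import (
    SOURCES,
    CoreGeneSet,
    EvidenceMatrix,
    GeneCoordinates,
    write_evidence_table,
)
from .gwa import SnpRecord, write_snp_table
from .tissue import TissueExpressionMatrix

#: Per-source score ranges matching the published data (min, max).
SOURCE_RANGES: dict[str, tuple[float, float]] = {
    "association": (0.0, 4.0),
    "linkage": (0.0, 4.6),
    "expression_human": (0.0, 4.6),
    "literature_human": (0.0, 6.0),
    "pathway": (0.0, 3.0),
    "expression_animal": (0.0, 5.6),
    "literature_animal": (0.0, 4.0),
}

BACKGROUND_NONZERO_PROB = 0.1

# sub-stream tags so evidence/GWA/tissue randomness stays decoupled
_STREAM_EVIDENCE, _STREAM_GWA, _STREAM_TISSUE, _STREAM_CORE = 0, 1, 2, 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults define the standard test conditions."""

    n_genes: int = 500
    n_true: int = 25
    informative_sources: tuple[str, ...] = ("association", "literature_human")
    effect: float = 3.0
    gwa_beta_a: float = 0.2
    n_snps_per_gene: int = 5
    n_core: int = 10
    seed: int = 0
    n_tissues: int = 20
    n_enriched_tissues: int = 3

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not (0 <= self.n_true <= self.n_genes):
            raise ValidationError("need 0 <= n_true <= n_genes")
        if not (2 <= self.n_core <= self.n_true):
            raise ValidationError("need 2 <= n_core <= n_true")
        if not (0 < self.gwa_beta_a <= 1):
            raise ValidationError("gwa_beta_a must be in (0, 1]")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.n_snps_per_gene < 1:
            raise ValidationError("n_snps_per_gene must be >= 1")
        bad = set(self.informative_sources) - set(SOURCES)
        if bad:
            raise ValidationError(f"unknown informative sources: {sorted(bad)}")
        if not (0 < self.n_enriched_tissues < self.n_tissues):
            raise ValidationError("need 0 < n_enriched_tissues < n_tissues")
        object.__setattr__(
            self, "informative_sources", tuple(self.informative_sources)
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted true-gene identifiers plus an echo of the config."""

    true_genes: tuple[str, ...]
    config: SyntheticConfig

    def __post_init__(self):
        if len(self.true_genes) != self.config.n_true:
            raise ValidationError("truth size does not match config.n_true")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _gene_names(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"G{i:0{width}d}" for i in range(1, n + 1))


def generate_evidence(cfg: SyntheticConfig) -> tuple[EvidenceMatrix, SyntheticTruth]:
    """Evidence matrix with sparse background and uplifted true genes.

    True genes receive ``cfg.effect`` added to their background draw in each
    informative source, clipped to that source's range; with ``effect=0``
    true and background genes are identically distributed.
    """
    rng = _rng(cfg, _STREAM_EVIDENCE)
    genes = _gene_names(cfg.n_genes)
    true_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_true, replace=False))
    scores = np.zeros((cfg.n_genes, len(SOURCES)))
    for c, source in enumerate(SOURCES):
        lo, hi = SOURCE_RANGES[source]
        nonzero = rng.random(cfg.n_genes) < BACKGROUND_NONZERO_PROB
        scores[:, c] = np.where(nonzero, rng.uniform(lo, hi, cfg.n_genes), 0.0)
        if source in cfg.informative_sources:
            scores[true_idx, c] = np.clip(scores[true_idx, c] + cfg.effect, lo, hi)
    truth = SyntheticTruth(tuple(genes[i] for i in true_idx), cfg)
    return EvidenceMatrix(genes, scores), truth


def sample_core_genes(truth: SyntheticTruth) -> CoreGeneSet:
    """Core gene set: ``n_core`` genes sampled from the planted truth."""
    cfg = truth.config
    rng = _rng(cfg, _STREAM_CORE)
    chosen = rng.choice(len(truth.true_genes), size=cfg.n_core, replace=False)
    return CoreGeneSet(tuple(truth.true_genes[i] for i in np.sort(chosen)))


#: gene body length and spacing on the synthetic chromosome (bp).  The
#: spacing leaves > 20 kb between neighbouring windows, so default-window
#: SNP mapping never assigns a SNP to two genes.
GENE_LENGTH = 10_000
GENE_SPACING = 60_000


def generate_gwa(
    truth: SyntheticTruth,
) -> tuple[list[SnpRecord], list[GeneCoordinates]]:
    """SNP table + gene coordinates on one synthetic chromosome.

    Each gene gets ``n_snps_per_gene`` SNPs inside its body; true-gene SNP
    p-values are Beta(gwa_beta_a, 1) (uniform when a = 1), background
    Uniform(0, 1).
    """
    cfg = truth.config
    rng = _rng(cfg, _STREAM_GWA)
    genes = _gene_names(cfg.n_genes)
    true_set = set(truth.true_genes)
    coords, snps = [], []
    for i, gene in enumerate(genes):
        start = 1 + i * GENE_SPACING
        end = start + GENE_LENGTH - 1
        coords.append(GeneCoordinates(gene=gene, chrom="1", start=start, end=end))
        positions = rng.integers(start, end + 1, size=cfg.n_snps_per_gene)
        if gene in true_set:
            pvals = rng.beta(cfg.gwa_beta_a, 1.0, size=cfg.n_snps_per_gene)
        else:
            pvals = rng.uniform(0.0, 1.0, size=cfg.n_snps_per_gene)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        for k, (pos, p) in enumerate(zip(positions, pvals)):
            snps.append(
                SnpRecord(f"rs{i * cfg.n_snps_per_gene + k + 1}", "1", int(pos), float(p))
            )
    return snps, coords


ENRICHED_PRESENT_TRUE = 0.8
ENRICHED_PRESENT_BACKGROUND = 0.4
BASELINE_PRESENT = 0.5


def generate_tissue_matrix(truth: SyntheticTruth) -> TissueExpressionMatrix:
    """Binary tissue presence matrix with a true-gene-enriched tissue block.

    The first ``n_enriched_tissues`` tissues (named ``enriched_*``) call true
    genes present with probability 0.8 vs 0.4 for background genes; all
    remaining tissues use 0.5 for every gene.
    """
    cfg = truth.config
    rng = _rng(cfg, _STREAM_TISSUE)
    genes = _gene_names(cfg.n_genes)
    is_true = np.isin(np.asarray(genes), np.asarray(truth.true_genes))
    n_enr = cfg.n_enriched_tissues
    tissues = tuple(
        f"enriched_{t + 1:02d}" if t < n_enr else f"tissue_{t + 1:02d}"
        for t in range(cfg.n_tissues)
    )
    probs = np.full((cfg.n_tissues, cfg.n_genes), BASELINE_PRESENT)
    probs[:n_enr, :] = np.where(
        is_true, ENRICHED_PRESENT_TRUE, ENRICHED_PRESENT_BACKGROUND
    )
    values = (rng.random((cfg.n_tissues, cfg.n_genes)) < probs).astype(np.int8)
    return TissueExpressionMatrix(tissues, genes, values)


def write_synthetic_inputs(cfg: SyntheticConfig, directory) -> dict[str, Path]:
    """Generate the full input bundle and write it in the formats the
    pipeline reads.  Returns the paths written (including ``truth.txt``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    evidence, truth = generate_evidence(cfg)
    core = sample_core_genes(truth)
    snps, coords = generate_gwa(truth)
    tissue = generate_tissue_matrix(truth)

    paths = {
        "evidence": directory / "evidence.tsv",
        "core_genes": directory / "core_genes.txt",
        "snps": directory / "snps.tsv",
        "gene_coords": directory / "gene_coords.tsv",
        "tissue": directory / "tissue.tsv",
        "truth": directory / "truth.txt",
    }
    write_evidence_table(evidence, paths["evidence"])
    paths["core_genes"].write_text(
        "# synthetic core genes (sampled from planted truth)\n"
        + "".join(f"{g}\n" for g in core.genes)
    )
    write_snp_table(snps, paths["snps"])
    with open(paths["gene_coords"], "w") as fh:
        for g in coords:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\n")
    tissue.write(paths["tissue"])
    paths["truth"].write_text("".join(f"{g}\n" for g in truth.true_genes))
    return paths
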