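"""SNP-to-gene mapping and random-set evaluation against GWA p-values.

A SNP is assigned to every gene whose body, extended by a flanking window
(20 kb by default), covers the SNP position; a gene's representative
association signal is the smallest p-value among its SNPs.  A prioritized
gene set is evaluated by comparing its p-value distribution with those of
random same-size gene sets drawn from the GWA-mapped universe: the summary
is the number of random sets whose p-values are significantly larger
(one-sided rank-sum), averaged over independent repeats.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evidence import GeneCoordinates
from .prioritize import RankedGeneList
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20_000


@dataclass(frozen=True)
class SnpRecord:
    """One SNP association result (1-based position, p in (0, 1])."""

    snp: str
    chrom: str
    position: int
    p_value: float

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"{self.snp}: position must be >= 1")
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"{self.snp}: p-value must be in (0, 1]")


@dataclass(frozen=True)
class GwaGeneTable:
    """Gene -> representative (minimum) association p-value."""

    pvalues: Mapping[str, float]

    def __post_init__(self):
        clean = {str(g).upper(): float(p) for g, p in self.pvalues.items()}
        if len(clean) != len(self.pvalues):
            raise ValidationError("duplicate genes in GWA gene table")
        for g, p in clean.items():
            if not (0 < p <= 1):
                raise ValidationError(f"{g}: p-value must be in (0, 1], got {p}")
        object.__setattr__(self, "pvalues", clean)

    def __len__(self) -> int:
        return len(self.pvalues)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.pvalues

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"gene": list(self.pvalues), "min_p": list(self.pvalues.values())}
        )
        return frame.sort_values("gene", ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GwaGeneTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(dict(zip(frame["gene"], frame["min_p"])))


@dataclass(frozen=True)
class EvaluationSummary:
    """Random-set comparison outcome.

    ``mean``/``sd``: mean and standard deviation, over repeats, of the count
    of random sets (out of ``n_random``) whose p-value distribution is
    significantly worse than the prioritized set's.
    """

    mean: float
    sd: float
    n_random: int
    repeats: int
    counts: tuple[int, ...]
    set_size: int

    def __post_init__(self):
        if not (0 <= self.mean <= self.n_random):
            raise ValidationError("mean must lie in [0, n_random]")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


def read_snp_table(path) -> list[SnpRecord]:
    """Read SNPs from TSV with columns ``snp, chrom, pos, p``."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SnpRecord(str(r.snp), r.chrom, int(r.pos), float(r.p))
        for r in frame.itertuples(index=False)
    ]


def write_snp_table(snps: Iterable[SnpRecord], path) -> None:
    pd.DataFrame(
        [(s.snp, s.chrom, s.position, s.p_value) for s in snps],
        columns=["snp", "chrom", "pos", "p"],
    ).to_csv(path, sep="\t", index=False)


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    coords: Sequence[GeneCoordinates],
    window: int = DEFAULT_WINDOW,
) -> GwaGeneTable:
    """Assign SNPs to genes within body +/- ``window`` bp; keep min p per gene.

    Window boundaries are inclusive on both ends.  SNPs on chromosomes
    absent from the coordinate table are skipped with a logged warning.
    Genes without any assigned SNP are absent from the result.  The mapping
    is independent of SNP input order.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    by_chrom: dict[str, list[GeneCoordinates]] = {}
    for g in coords:
        by_chrom.setdefault(g.chrom, []).append(g)

    best: dict[str, float] = {}
    unknown: set[str] = set()
    for snp in snps:
        genes = by_chrom.get(snp.chrom)
        if genes is None:
            unknown.add(snp.chrom)
            continue
        for g in genes:
            if g.start - window <= snp.position <= g.end + window:
                prev = best.get(g.gene)
                if prev is None or snp.p_value < prev:
                    best[g.gene] = snp.p_value
    if unknown:
        logger.warning(
            "skipped SNPs on chromosomes absent from the coordinate table: %s",
            sorted(unknown),
        )
    return GwaGeneTable(best)


def evaluate_prioritized_set(
    ranking: RankedGeneList,
    gwa: GwaGeneTable,
    j: int,
    n_random: int = 1000,
    repeats: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
    alternative: str = "less",
) -> EvaluationSummary:
    """Compare the top-``j`` prioritized genes against random gene sets.

    The prioritized sample holds the GWA p-values of the top-``j`` genes of
    the ranking that are present in the GWA table (absent genes are
    dropped).  Each repeat draws ``n_random`` random gene sets of the same
    post-drop size, uniformly without replacement within a set, from the
    full GWA gene universe, and counts how many are significantly worse
    (one-sided rank-sum p < ``alpha`` by default).  Repeats use independent
    derived random streams so the whole evaluation is reproducible from one
    seed.
    """
    if n_random < 1 or repeats < 1:
        raise ValidationError("n_random and repeats must be >= 1")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    if j < 1 or j > len(gwa):
        raise ValidationError(f"set size j={j} outside 1..{len(gwa)} (GWA universe)")
    top = ranking.top(j)
    x = np.asarray([gwa.pvalues[g] for g in top if g in gwa], dtype=float)
    if x.size == 0:
        raise ValidationError("no top-j gene is present in the GWA table")
    universe = np.asarray(list(gwa.pvalues.values()), dtype=float)
    if x.size > universe.size:
        raise ValidationError("prioritized set larger than GWA universe")

    counts = []
    for r in range(repeats):
        rng = np.random.default_rng(r if seed is None else [int(seed), r])
        hits = 0
        for _ in range(n_random):
            y = rng.choice(universe, size=x.size, replace=False)
            if wilcoxon_rank_sum(x, y, alternative=alternative) < alpha:
                hits += 1
        counts.append(hits)
    arr = np.asarray(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if repeats > 1 else 0.0
    return EvaluationSummary(
        mean=float(arr.mean()),
        sd=sd,
        n_random=n_random,
        repeats=repeats,
        counts=tuple(int(c) for c in counts),
        set_size=int(x.size),
    )
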