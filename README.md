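# depgenes

Multi-source evidence integration and candidate-gene prioritization for
complex disease genetics, built around the weighted combined-score framework
used to derive the DEPgenes list for major depressive disorder.

## The problem

A decade of association studies, linkage scans, expression arrays,
literature and pathway curation produces thousands of inconsistent candidate
genes per disease — too heterogeneous for meta-analysis. This package
implements the alternative: score each gene per data source, learn how much
each source should count, and rank genes by a single combined score.

For gene *g* with per-source scores *S₁…S₇* over the seven sources
(association, linkage, human expression, human literature, pathway, animal
expression, animal literature):

```
combined(g) = Σᵢ preWeightᵢ · Sᵢ(g) · Wᵢ
```

* `preWeight` ∈ [0.5, 1.5] — fixed per-source pre-multipliers adjusting for
  unequal raw score ranges (default (1.5, 1, 1.5, 0.5, 1, 1, 0.5)).
* `W` — an integer weight vector from the exhaustive grid {1..d}⁷
  (d = 8 at full scale: 8⁷ = 2,097,152 candidates).

The optimal `W` is chosen in two stages:

1. **Core-gene concentration.** For each `W`, all genes are ranked by
   combined score; a matrix survives if the ⌈φ·K⌉-th of the K core genes
   (a small expert-curated positive set) ranks within the top ⌈η·N⌉
   candidates. Positions *j* (⌈φ·K⌉-th core gene) and *l* (last core gene)
   are reported per matrix.
2. **GWA random-set evaluation.** Each survivor's top-*j* genes are compared
   against 1000 random same-size gene sets drawn from the GWA-mapped
   universe (gene-level p = min over SNPs within the gene ± 20 kb); the
   count of random sets with significantly worse p-values (one-sided
   Wilcoxon rank-sum, p < 0.05), averaged over 10 repeats, scores the
   matrix. Highest mean wins (ties: smaller *j*, then *l*).

The final list contains every gene whose combined score reaches a cutoff
placed where the core-gene and candidate score distributions separate.
At the published scale this machinery selects weight matrix [2,1,1,8,1,1,7]
(effective weights 3, 1, 1.5, 4, 1, 1, 3.5) and 169 genes at cutoff 15; that
printed table and the 14-gene core set ship as package fixtures.

A synthetic-data generator with planted truth (`depgenes.synthetic`) stands
in for the study's curated inputs and restricted GWA data, so the whole
pipeline is testable end to end.

## Worked example

`examples/prioritize_synthetic.py` generates 500 genes with 25 planted
disease genes (signal in the association and human-literature sources),
then runs the full pipeline on the reduced d = 4 grid:

```
weight matrices scanned : 16384 (4^7)
passed core criterion   : 5245
optimal weight matrix   : [4,1,1,4,1,1,1]
core positions          : j=22, l=24
evaluation mean         : 100.0 of 100 random sets beaten (sd 0.0)
suggested cutoff        : 24.00
genes selected          : 26
precision vs truth      : 0.96
```

The search up-weights exactly the two planted informative sources, the
top-ranked set beats every random gene set in the GWA comparison, and 25 of
the 26 genes selected at the separation-suggested cutoff are planted true
genes. The other scripts in `examples/` walk through scoring raw evidence,
SNP-to-gene min-p mapping, tissue-profile comparison and rank-stability
diagnostics, each printing and explaining its numbers.

A thin CLI wraps the same pipeline for shell use
(`depgenes synth | score | prioritize | evaluate-gwa | select | tissue`);
run `depgenes --help`.

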