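"""SNP-to-gene mapping and random-set evaluation of an enriched gene set.

A gene's representative association signal is the minimum p-value over the
SNPs inside its body +/- 20 kb.  A prioritized set is judged by how many of
1000 random same-size gene sets show a significantly worse p-value
distribution (one-sided Wilcoxon rank-sum at alpha = 0.05).
"""
import depgenes as dg

cfg = dg.SyntheticConfig(seed=3)
_, truth = dg.generate_evidence(cfg)
snps, coords = dg.generate_gwa(truth)

gwa = dg.map_snps_to_genes(snps, coords, window=20_000)
print(f"{len(gwa)} genes mapped from {len(snps)} SNPs")

# rank the planted true genes on top, background after them
ordered = list(truth.true_genes) + [
    g for g in gwa.pvalues if g not in set(truth.true_genes)
]
ranking = dg.RankedGeneList(
    tuple(ordered), tuple(float(len(ordered) - i) for i in range(len(ordered)))
)

summary = dg.evaluate_prioritized_set(
    ranking, gwa, j=cfg.n_true, n_random=1000, repeats=10, seed=5
)
print(f"random sets beaten: mean {summary.mean:.1f} / {summary.n_random} "
      f"(sd {summary.sd:.1f} over {summary.repeats} repeats)")
print()
print("Planted true genes carry Beta(0.2, 1) SNP p-values, so nearly every")
print("random set loses; an unenriched set would beat only ~50 of 1000.")
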