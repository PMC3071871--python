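"""Compare tissue-expression profiles of selected vs background genes.

Uses a binary tissues x genes presence matrix; per-tissue expression
proportions of the two lists are compared with a paired Wilcoxon
signed-rank test across tissues.
"""
import depgenes as dg

cfg = dg.SyntheticConfig(seed=11)
_, truth = dg.generate_evidence(cfg)
tissue = dg.generate_tissue_matrix(truth)

background = [g for g in tissue.genes if g not in set(truth.true_genes)]
cmp = dg.compare_tissue_profiles(tissue, truth.true_genes, background,
                                 alternative="greater")

print("top per-tissue differences (true - background proportion):")
for name, diff in cmp.differences.sort_values(ascending=False).head(5).items():
    print(f"  {name:14s} {diff:+.3f}")
print(f"one-sided signed-rank p = {cmp.p_value:.3g}")
print()
print("The enriched_* tissues are constructed with 0.8 vs 0.4 presence")
print("probability for true vs background genes; the top differences")
print("recover exactly that block.")
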