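"""Full prioritization pipeline on a synthetic dataset with planted truth.

Generates evidence for 500 genes (25 planted disease genes enriched in the
association and human-literature sources), searches the 4^7 weight grid for
matrices concentrating a 10-gene core set at the top of the combined-score
ranking, evaluates survivors against synthetic GWA p-values by random-set
comparison, and cuts the final gene list where core and candidate score
distributions separate.
"""
import numpy as np

import depgenes as dg

cfg = dg.SyntheticConfig(seed=7)
evidence, truth = dg.generate_evidence(cfg)
core = dg.sample_core_genes(truth)
snps, coords = dg.generate_gwa(truth)
gwa = dg.map_snps_to_genes(snps, coords)  # min p per gene, 20 kb window

run = dg.run_prioritization(
    evidence, core, dg.load_default_preweight(), gwa,
    phi=0.9, eta=0.08, d=4, n_random=100, repeats=3, seed=1, max_evaluate=20,
)

print(f"weight matrices scanned : {len(run.selection)} (4^7)")
print(f"passed core criterion   : {sum(r.passed for r in run.selection)}")
print(f"optimal weight matrix   : {run.optimal.weights}")
print(f"core positions          : j={run.optimal.position_j}, l={run.optimal.position_l}")
print(f"evaluation mean         : {run.optimal_summary.mean:.1f} of "
      f"{run.optimal_summary.n_random} random sets beaten "
      f"(sd {run.optimal_summary.sd:.1f})")
print(f"suggested cutoff        : {run.cutoff:.2f}")
print(f"genes selected          : {len(run.depgenes)}")

truth_set = set(truth.true_genes)
precision = np.mean([g in truth_set for g in run.depgenes.genes])
print(f"precision vs truth      : {precision:.2f}")
print()
print("The optimal matrix puts high weight on the two planted informative")
print("sources; the selected list recovers the planted disease genes with")
print("high precision at the separation-suggested cutoff.")
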