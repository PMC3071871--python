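"""Reference experiments on synthetic data.

Two canned experiments the package uses to validate itself end to end:

* :func:`planted_signal_replicate` — one parameter-recovery run: generate a
  planted-truth dataset, run the full pipeline on a reduced weight grid and
  report whether the informative sources were driven to the grid maximum
  and how precise the selected gene list is against the planted truth.
* :func:`null_rejection_rate` — calibration of the random-set evaluation:
  under a null where the "prioritized" set is an arbitrary subset of a
  uniform GWA universe, the fraction of random sets called significantly
  worse should match the test level alpha.  Each run redraws the
  prioritized set itself (the run-to-run spread is dominated by that
  outer randomness, which is why the experiment averages over independent
  runs rather than inflating a single run's comparisons).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence import load_default_preweight
from .gwa import GwaGeneTable, evaluate_prioritized_set, map_snps_to_genes
from .pipeline import run_prioritization
from .prioritize import RankedGeneList
from .synthetic import SyntheticConfig, generate_evidence, generate_gwa, sample_core_genes

#: Conditions of the standard parameter-recovery experiment.
RECOVERY_DEFAULTS = dict(
    phi=0.9, eta=0.08, d=4, n_random=50, repeats=2, max_evaluate=20
)


@dataclass(frozen=True)
class RecoveryReplicate:
    seed: int
    optimal_weights: tuple[int, ...]
    informative_at_grid_max: bool
    precision: float
    position_j: int
    evaluation_mean: float


def planted_signal_replicate(seed: int, **overrides) -> RecoveryReplicate:
    """Run one seeded parameter-recovery replicate at the standard conditions."""
    params = {**RECOVERY_DEFAULTS, **overrides}
    d = params.pop("d")
    cfg = SyntheticConfig(seed=seed)
    evidence, truth = generate_evidence(cfg)
    core = sample_core_genes(truth)
    snps, coords = generate_gwa(truth)
    gwa = map_snps_to_genes(snps, coords)
    run = run_prioritization(
        evidence, core, load_default_preweight(), gwa, d=d, seed=seed, **params
    )
    weights = run.optimal.weights.values
    informative_idx = [
        i for i, s in enumerate(evidence.sources) if s in cfg.informative_sources
    ]
    at_max = all(weights[i] == d for i in informative_idx)
    truth_set = set(truth.true_genes)
    precision = float(
        np.mean([g in truth_set for g in run.depgenes.genes])
    ) if len(run.depgenes) else 0.0
    return RecoveryReplicate(
        seed=seed,
        optimal_weights=weights,
        informative_at_grid_max=at_max,
        precision=precision,
        position_j=run.optimal.position_j,
        evaluation_mean=run.optimal_summary.mean,
    )


def recovery_experiment(
    n_replicates: int = 10, base_seed: int = 0, **overrides
) -> list[RecoveryReplicate]:
    """Independent seeded replicates of the parameter-recovery experiment."""
    return [
        planted_signal_replicate(base_seed + r, **overrides)
        for r in range(n_replicates)
    ]


def null_rejection_rate(
    seed: int = 0,
    n_runs: int = 10,
    n_random: int = 200,
    n_genes: int = 2000,
    set_size: int = 150,
    alpha: float = 0.05,
) -> tuple[float, float, list[float]]:
    """Type-I calibration of the random-set evaluation.

    Returns (mean rejection rate, standard error of that mean over runs,
    per-run rates).  Under the null the mean rate estimates alpha.
    """
    rates = []
    for r in range(n_runs):
        rng = np.random.default_rng([int(seed), 10_000 + r])
        genes = tuple(f"G{i:05d}" for i in range(n_genes))
        pvals = rng.uniform(np.finfo(float).tiny, 1.0, n_genes)
        order = rng.permutation(n_genes)  # ranking unrelated to the p-values
        ranking = RankedGeneList(
            tuple(genes[i] for i in order),
            tuple(float(n_genes - k) for k in range(n_genes)),
        )
        gwa = GwaGeneTable(dict(zip(genes, pvals)))
        summary = evaluate_prioritized_set(
            ranking, gwa, j=set_size, n_random=n_random, repeats=1,
            alpha=alpha, seed=int(rng.integers(2**31)),
        )
        rates.append(summary.mean / n_random)
    rates_arr = np.asarray(rates)
    sem = float(rates_arr.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
    return float(rates_arr.mean()), sem, rates
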