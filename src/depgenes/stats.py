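"""Rank tests used by the evaluation stages.

Both tests handle ties by mid-ranks and switch between an exact null
distribution on small samples and a tie-corrected normal approximation with
continuity correction on larger ones.  They are implemented here rather than
delegated because the exact branches must accept tied data (the p-values fed
in are min-p statistics that can repeat); scipy's exact methods decline ties.

* :func:`wilcoxon_rank_sum` — two-sample test that one sample is
  stochastically smaller; exact by enumeration of all C(n, nx) group
  assignments for total n <= 20.
* :func:`wilcoxon_signed_rank` — paired test on differences; exact by
  dynamic programming over the signed-rank sum distribution for <= 25
  non-zero pairs.
"""
from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ValidationError

EXACT_RANKSUM_MAX_N = 20
EXACT_SIGNEDRANK_MAX_N = 25

_ALTERNATIVES = ("less", "greater", "two-sided")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``alternative="less"`` tests whether ``x`` is stochastically smaller
    than ``y``.  Exact enumeration (all group assignments, mid-ranks) when
    the pooled size is at most 20; otherwise normal approximation with tie
    correction and continuity correction.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires two non-empty samples")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())

    if n <= EXACT_RANKSUM_MAX_N:
        return _ranksum_exact(ranks, nx, w, alternative)

    mean = nx * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "less":
        return float(norm.cdf((w - mean + 0.5) / sd))
    if alternative == "greater":
        return float(norm.sf((w - mean - 0.5) / sd))
    z = (abs(w - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def _ranksum_exact(ranks: np.ndarray, nx: int, w_obs: float, alternative: str) -> float:
    """Exact p by enumerating every assignment of nx labels to the pooled ranks."""
    n = ranks.size
    total = math.comb(n, nx)
    # count assignments by rank-sum; floats are exact here (sums of halves)
    n_le = n_ge = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n), nx):
        s = ranks[list(combo)].sum()
        if s <= w_obs + eps:
            n_le += 1
        if s >= w_obs - eps:
            n_ge += 1
    if alternative == "less":
        return n_le / total
    if alternative == "greater":
        return n_ge / total
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_signed_rank(
    differences: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Paired Wilcoxon signed-rank p-value on a vector of differences.

    Zero differences are dropped; if none remain the test is degenerate and
    returns 1.0 with a warning.  ``alternative="greater"`` tests whether the
    differences are shifted above zero.  Exact for <= 25 non-zero pairs
    (dynamic programming over the signed-rank sum, valid under ties),
    otherwise tie-corrected normal approximation.
    """
    _check_alternative(alternative)
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValidationError("signed-rank test requires at least one difference")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; signed-rank test is degenerate, p = 1")
        return 1.0
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_SIGNEDRANK_MAX_N:
        return _signed_rank_exact(ranks, w_plus, alternative)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if var == 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        return float(norm.sf((w_plus - mean - 0.5) / sd))
    if alternative == "less":
        return float(norm.cdf((w_plus - mean + 0.5) / sd))
    z = (abs(w_plus - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def _signed_rank_exact(ranks: np.ndarray, w_obs: float, alternative: str) -> float:
    """Exact signed-rank p over all 2^n sign assignments via convolution.

    Mid-ranks are doubled so every rank is an integer; the null distribution
    of the (doubled) positive-rank sum is built by polynomial convolution.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total_sum = int(r2.sum())
    counts = np.zeros(total_sum + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in r2:
        upper += r
        counts[r : upper + 1] += counts[0 : upper + 1 - r]
    counts /= counts.sum()
    obs = int(round(2 * w_obs))
    p_le = float(counts[: obs + 1].sum())
    p_ge = float(counts[obs:].sum())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))
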