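"""Nonparametric statistics used throughout the coherence pipeline.

Self-contained, tie-corrected implementations of the rank-based tests the
analysis relies on (Friedman, Wilcoxon signed-rank, Kruskal-Wallis), the
exact multinomial goodness-of-fit test by full enumeration, Cohen's d, and
Bonferroni adjustment.  Each routine is written from the defining formulas
so that library implementations can serve as independent cross-checks in
the test suite.

Conventions
-----------
* All p-values are two-tailed unless stated otherwise.
* Effect size for Z-based tests is r = |Z| / sqrt(N), with N the number of
  observations entering the test.
* Degenerate inputs (complete ties) return statistic 0 and p = 1 with a
  warning instead of failing: thresholded coherence maps can be constant.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata


class DegenerateDataWarning(UserWarning):
    """Raised (as a warning) when a test input is completely tied."""


@dataclass
class StatResult:
    """Outcome of one hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (chi-square for Friedman, H for Kruskal-Wallis,
        W+ for Wilcoxon).
    df : int or None
        Degrees of freedom where the reference distribution has them.
    p : float
        Two-tailed p-value in [0, 1].
    effect_size_r : float or None
        r = |Z|/sqrt(N) where a Z statistic is defined.
    n : int
        Number of observations (blocks, pooled samples, or non-zero pairs)
        that entered the test.
    correction : str
        Multiple-comparison correction applied: "none" or "bonferroni(m)".
    degenerate : bool
        True when the input was completely tied and the conventional
        (0, p=1) result was returned.
    zstatistic : float or None
        Normal-approximation Z where defined (Wilcoxon).
    """

    statistic: float
    df: Optional[int]
    p: float
    effect_size_r: Optional[float] = None
    n: int = 0
    correction: str = "none"
    degenerate: bool = False
    zstatistic: Optional[float] = None


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def friedman_test(data: np.ndarray) -> StatResult:
    """Tie-corrected Friedman test on a blocks x conditions matrix.

    Ranks are assigned within each block (row); the chi-square statistic

        chi2 = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C

    with the tie correction C = 1 - sum(t^3 - t) / (n k (k^2 - 1)) over tie
    groups within blocks, is referred to a chi-square with k-1 df.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("Friedman test requires a 2-D blocks x conditions matrix")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 conditions and >= 2 blocks")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed; drop incomplete blocks first")

    ranks = np.apply_along_axis(rankdata, 1, x)
    colsums = ranks.sum(axis=0)

    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k * k - 1))
    if correction <= 0:
        warnings.warn("all cells tied; returning degenerate result",
                      DegenerateDataWarning)
        return StatResult(0.0, k - 1, 1.0, n=n, degenerate=True)

    stat = (12.0 / (n * k * (k + 1)) * np.sum(colsums**2) - 3.0 * n * (k + 1))
    stat /= correction
    p = float(chi2.sf(stat, k - 1))
    return StatResult(float(stat), k - 1, p, n=n)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_exact_sf(ranks2: np.ndarray, w2: float) -> tuple[float, float]:
    """Exact P(W+ <= w) and P(W+ >= w) by the generating-polynomial DP.

    ``ranks2`` are the (possibly tied, hence half-integer) ranks doubled to
    integers; ``w2`` is the observed doubled W+.  Enumerates the conditional
    null over all 2^N sign assignments via convolution of (1 + z^{2 r_i}).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    return float(counts[: w2i + 1].sum()), float(counts[w2i:].sum())


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    mu0: float = 0.0,
    two_tailed: bool = True,
    zero_method: str = "drop",
    exact_limit: int = 25,
    continuity: bool = False,
) -> StatResult:
    """Wilcoxon signed-rank test, paired or one-sample against ``mu0``.

    Zero differences are dropped by default (``zero_method="drop"``, the
    classic reduced-sample procedure); ``"pratt"`` ranks zeros and removes
    them from the statistic.  The exact sign-flip enumeration is used for
    N <= ``exact_limit`` (drop mode); otherwise the tie-corrected normal
    approximation, without continuity correction unless requested.  The
    effect size r = |Z|/sqrt(N) is always reported from the Z path.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x - mu0

    if zero_method not in ("drop", "pratt"):
        raise ValueError("zero_method must be 'drop' or 'pratt'")

    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all differences zero; degenerate Wilcoxon result",
                      DegenerateDataWarning)
        return StatResult(0.0, None, 1.0, effect_size_r=0.0, n=0,
                          degenerate=True, zstatistic=0.0)

    if zero_method == "drop":
        d_used = d[nonzero]
        ranks = rankdata(np.abs(d_used))
        wplus = float(ranks[d_used > 0].sum())
        n = d_used.size
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d_used), return_counts=True)
        tie_adj = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_adj
    else:  # pratt
        ranks_all = rankdata(np.abs(d))
        wplus = float(ranks_all[d > 0].sum())
        n = int(nonzero.sum())
        nz = d.size - n
        ntot = d.size
        mean = (ntot * (ntot + 1) - nz * (nz + 1)) / 4.0
        _, tie_counts = np.unique(np.abs(d[nonzero]), return_counts=True)
        tie_adj = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = (ntot * (ntot + 1) * (2 * ntot + 1)
               - nz * (nz + 1) * (2 * nz + 1)) / 24.0 - tie_adj

    if var <= 0:
        warnings.warn("zero variance in signed ranks; degenerate result",
                      DegenerateDataWarning)
        return StatResult(wplus, None, 1.0, effect_size_r=0.0, n=n,
                          degenerate=True, zstatistic=0.0)

    diff = wplus - mean
    if continuity:
        diff -= 0.5 * np.sign(diff)
    z = diff / math.sqrt(var)

    if zero_method == "drop" and n <= exact_limit:
        ranks2 = np.round(2 * rankdata(np.abs(d[nonzero]))).astype(int)
        lo, hi = _signed_rank_exact_sf(np.asarray(ranks2), 2 * wplus)
        p = min(1.0, 2.0 * min(lo, hi)) if two_tailed else hi
    else:
        p = 2.0 * norm.sf(abs(z)) if two_tailed else norm.sf(z)
        p = min(1.0, float(p))

    r = abs(z) / math.sqrt(n)
    return StatResult(wplus, None, float(p), effect_size_r=float(r), n=n,
                      zstatistic=float(z))


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Tie-corrected Kruskal-Wallis H test across independent groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")

    pooled = np.concatenate(arrays)
    ntot = pooled.size
    ranks = rankdata(pooled)

    h = 0.0
    start = 0
    for a in arrays:
        rsum = ranks[start:start + a.size].sum()
        h += rsum * rsum / a.size
        start += a.size
    h = 12.0 / (ntot * (ntot + 1)) * h - 3.0 * (ntot + 1)

    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (ntot**3 - ntot)
    if tie <= 0:
        warnings.warn("all observations tied; degenerate Kruskal-Wallis",
                      DegenerateDataWarning)
        return StatResult(0.0, len(arrays) - 1, 1.0, n=ntot, degenerate=True)
    h /= tie
    df = len(arrays) - 1
    return StatResult(float(h), df, float(chi2.sf(h, df)), n=ntot)


# ---------------------------------------------------------------------------
# Exact multinomial goodness-of-fit
# ---------------------------------------------------------------------------

def _log_multinomial_pmf(counts: tuple[int, ...], logp: np.ndarray,
                         lognfact: float) -> float:
    out = lognfact
    for c, lp in zip(counts, logp):
        if c:
            if np.isneginf(lp):
                return -np.inf
            out += c * lp - math.lgamma(c + 1)
        else:
            out -= 0.0
    return out


def exact_multinomial(counts: Sequence[int], probs: Sequence[float],
                      max_outcomes: int = 5_000_000) -> float:
    """Exact multinomial goodness-of-fit p by full enumeration.

    Enumerates every composition of n = sum(counts) into k categories and
    sums the multinomial probabilities of all outcomes at least as extreme
    as the observed one, where extremeness is probability ordering:
    P(outcome) <= P(observed) * (1 + 1e-12), the float guard keeping
    equal-probability outcomes (including the observed one) in the tail.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative integers")
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(counts),):
        raise ValueError("probs must match counts in length")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    if (probs < 0).any():
        raise ValueError("probabilities must be non-negative")

    n = sum(counts)
    k = len(counts)
    if math.comb(n + k - 1, k - 1) > max_outcomes:
        raise ValueError("outcome space too large for full enumeration")

    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    lognfact = math.lgamma(n + 1)
    log_obs = _log_multinomial_pmf(counts, logp, lognfact)
    if np.isneginf(log_obs):
        return 0.0
    thresh = log_obs + math.log1p(1e-12)

    total = 0.0
    for head in itertools.product(range(n + 1), repeat=k - 1):
        s = sum(head)
        if s > n:
            continue
        outcome = head + (n - s,)
        lp = _log_multinomial_pmf(outcome, logp, lognfact)
        if lp <= thresh:
            total += math.exp(lp)
    return min(1.0, float(total))


# ---------------------------------------------------------------------------
# Effect sizes and corrections
# ---------------------------------------------------------------------------

def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Cohen's d with the pooled (n-1) standard deviation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = math.sqrt(((a.size - 1) * va + (b.size - 1) * vb)
                       / (a.size + b.size - 2))
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(diff / pooled)


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: p * m capped at 1, for a family of m tests."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)
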