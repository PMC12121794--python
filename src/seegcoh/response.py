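"""Responder classification, SNR profiling, hub detection, and seed maps.

These are the headline read-outs of the stimulation-evoked coherence
analysis:

* a *responder* electrode pair has Cohen's d > 0.2 (strict) for its
  per-epoch MSC during a stimulation condition versus baseline;
* responder counts become percentages of total pairs per subject, whose
  cross-subject consistency per condition is summarized as SNR = mu/sigma
  and tested against a label-shuffling permutation null;
* the condition at which each subject's responder percentage peaks gives a
  best-frequency ranking tested with the exact multinomial;
* *hub* region pairs exceed the global (brain-wide) mean delta by >= 2 SD,
  and a hub region appears in two or more such pairs;
* *seed maps* show each seed region's delta to every covered region, masked
  to |delta| > 0.01, and are compared across conditions by Kruskal-Wallis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .npstats import (DegenerateDataWarning, StatResult,
                      bonferroni_adjust, exact_multinomial, kruskal_wallis)
from .preprocessing import BASELINE


@dataclass
class HubResult:
    """Region pairs >= 2 SD above the global mean delta, and hub regions."""

    condition: str
    band: str
    mean: float
    sd: float
    threshold: float
    pairs: List[Tuple[str, str]] = field(default_factory=list)
    hub_regions: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Responders
# ---------------------------------------------------------------------------

def responder_map(pair_table: pd.DataFrame, threshold: float = 0.2,
                  baseline_label: str = BASELINE
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Classify responder pairs from a per-epoch MSC table.

    Cohen's d compares each pair's per-epoch MSC distribution during a
    condition against its baseline distribution; responder iff d > threshold
    (strictly).  Pairs with fewer than 2 valid epochs on either side are
    excluded from numerator and denominator alike.

    Returns (per-pair d table, per-(condition, band) percentage summary).
    """
    stats = (pair_table.groupby(["chan_a", "chan_b", "condition", "band"],
                                sort=False)["msc"]
             .agg(["mean", "var", "size"]).reset_index())
    base = stats[stats["condition"] == baseline_label]
    stim = stats[stats["condition"] != baseline_label]
    merged = stim.merge(base[["chan_a", "chan_b", "band", "mean", "var",
                              "size"]],
                        on=["chan_a", "chan_b", "band"], how="inner",
                        suffixes=("_s", "_b"))
    merged = merged[(merged["size_s"] >= 2) & (merged["size_b"] >= 2)]
    if merged.empty:
        raise ValueError("no pair had enough valid epochs")
    ns, nb = merged["size_s"], merged["size_b"]
    pooled = np.sqrt(((ns - 1) * merged["var_s"] + (nb - 1) * merged["var_b"])
                     / (ns + nb - 2))
    diff = merged["mean_s"] - merged["mean_b"]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, diff / pooled,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    pair_d = merged[["chan_a", "chan_b", "condition", "band"]].copy()
    pair_d["d"] = d
    pair_d["responder"] = d > threshold
    summary = (pair_d.groupby(["condition", "band"], sort=False)
               .agg(n_responders=("responder", "sum"),
                    n_pairs=("responder", "size")).reset_index())
    summary["percentage"] = 100.0 * summary["n_responders"] / summary["n_pairs"]
    return pair_d, summary


def best_frequency_ranking(percentages: pd.DataFrame, band: str,
                           conditions: Sequence[str]
                           ) -> Tuple[Dict[str, int], float]:
    """Counts of subjects whose responder percentage peaks at each condition.

    ``percentages`` is long format (subject, condition, band, percentage).
    Ties at the maximum go to the earliest condition in ``conditions`` (the
    lowest vibration frequency) with a warning.  The second return value is
    the exact multinomial p against uniform category probabilities.
    """
    sub = percentages[percentages["band"] == band]
    counts = {c: 0 for c in conditions}
    for subject, g in sub.groupby("subject"):
        by_cond = g.set_index("condition")["percentage"]
        missing = [c for c in conditions if c not in by_cond.index]
        if missing:
            raise ValueError(f"subject {subject} lacks conditions {missing}")
        vals = np.array([by_cond[c] for c in conditions])
        top = np.flatnonzero(vals == vals.max())
        if top.size > 1:
            warnings.warn(f"subject {subject}: tie at the maximum; assigned "
                          f"to {conditions[top[0]]}")
        counts[conditions[top[0]]] += 1
    p = exact_multinomial(list(counts.values()),
                          [1.0 / len(conditions)] * len(conditions))
    return counts, p


# ---------------------------------------------------------------------------
# SNR profile and permutation test
# ---------------------------------------------------------------------------

def _snr(matrix: np.ndarray, ddof: int) -> np.ndarray:
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mu / sd, np.inf)


def snr_profile(percent_matrix: np.ndarray, conditions: Sequence[str],
                sd_mode: str = "sample") -> pd.DataFrame:
    """SNR = mean/SD of responder percentages across subjects, per condition.

    ``percent_matrix`` is subjects x conditions.  Conditions are ranked in
    descending SNR; a zero-SD condition is flagged degenerate (infinite SNR)
    and should be excluded from permutation comparison by the caller.
    """
    m = np.asarray(percent_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(conditions):
        raise ValueError("matrix must be subjects x conditions")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    ddof = 1 if sd_mode == "sample" else 0
    snr = _snr(m, ddof)
    degenerate = ~np.isfinite(snr)
    if degenerate.any():
        warnings.warn("zero cross-subject SD; SNR undefined for some "
                      "condition(s)", DegenerateDataWarning)
    order = (-snr).argsort()
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(conditions) + 1)
    return pd.DataFrame({"condition": list(conditions), "snr": snr,
                         "rank": rank, "degenerate": degenerate})


def permutation_snr_test(percent_matrix: np.ndarray, n_perm: int = 10000,
                         seed: int = 0, mode: str = "strict",
                         sd_mode: str = "sample") -> np.ndarray:
    """Permutation p per condition for the cross-subject SNR.

    Each iteration independently shuffles every subject's condition labels
    (row permutation) and recomputes per-condition SNR.  Under the strict
    rule, p is the proportion of iterations whose permuted SNR exceeds the
    observed SNR; ``mode="geq"`` counts ties as exceedances (so a fully
    degenerate matrix gives p = 1 rather than 0); ``mode="add_one"`` applies
    the (b+1)/(n+1) correction, which avoids p = 0 and is the recommended
    estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("strict", "geq", "add_one"):
        raise ValueError("mode must be 'strict', 'geq' or 'add_one'")
    m = np.asarray(percent_matrix, dtype=float)
    n_subj, n_cond = m.shape
    ddof = 1 if sd_mode == "sample" else 0
    observed = _snr(m, ddof)
    if np.ptp(m) == 0:
        warnings.warn("constant matrix: permutation null is degenerate "
                      "(strict rule yields p = 0)", DegenerateDataWarning)

    rng = np.random.default_rng(seed)
    # Independent row permutations: argsort of iid uniforms per (iter, row).
    u = rng.random((n_perm, n_subj, n_cond))
    idx = np.argsort(u, axis=-1)
    permuted = np.take_along_axis(
        np.broadcast_to(m, (n_perm, n_subj, n_cond)), idx, axis=-1)
    mu = permuted.mean(axis=1)
    sd = permuted.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_perm = np.where(sd > 0, mu / sd, np.inf)
    if mode == "geq":
        return (snr_perm >= observed).sum(axis=0) / n_perm
    exceed = (snr_perm > observed).sum(axis=0)
    if mode == "strict":
        return exceed / n_perm
    return (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Hubs and seed maps
# ---------------------------------------------------------------------------

def hub_pairs(group_deltas: pd.DataFrame, condition: str, band: str,
              sd_mode: str = "sample", include_within_region: bool = False
              ) -> HubResult:
    """Region pairs whose delta is >= 2 SD above the brain-wide mean.

    The global distribution is the same (condition, band) slice of the group
    table being thresholded.  Hub regions take part in >= 2 qualifying pairs.
    """
    sub = group_deltas[(group_deltas["condition"] == condition)
                       & (group_deltas["band"] == band)]
    if not include_within_region:
        sub = sub[sub["region_a"] != sub["region_b"]]
    deltas = sub["delta"].to_numpy()
    if deltas.size == 0:
        raise ValueError(f"no pairs for condition={condition!r}, band={band!r}")
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1 if sd_mode == "sample" else 0))
    if sd == 0:
        warnings.warn("degenerate global distribution (SD = 0); no hubs",
                      DegenerateDataWarning)
        return HubResult(condition, band, mean, sd, np.inf)
    threshold = mean + 2.0 * sd
    qual = sub[sub["delta"] >= threshold]
    pairs = [(r.region_a, r.region_b) for r in qual.itertuples()]
    counts: Dict[str, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    hubs = sorted(r for r, c in counts.items() if c >= 2)
    return HubResult(condition, band, mean, sd, threshold, pairs, hubs)


def seed_map(region_deltas: pd.DataFrame, seed_region: str,
             threshold: float = 0.01) -> pd.DataFrame:
    """Deltas from one seed region to every covered region, thresholded.

    Only entries with |delta| strictly above ``threshold`` survive; the sign
    is preserved.  Raises if the seed region has no coverage.
    """
    touches = ((region_deltas["region_a"] == seed_region)
               | (region_deltas["region_b"] == seed_region))
    if not touches.any():
        raise ValueError(f"seed region {seed_region!r} has no coverage")
    sub = region_deltas[touches
                        & (region_deltas["region_a"]
                           != region_deltas["region_b"])].copy()
    sub["target"] = np.where(sub["region_a"] == seed_region,
                             sub["region_b"], sub["region_a"])
    sub = sub[np.abs(sub["delta"]) > threshold]
    cols = ["condition", "band", "target", "delta"]
    return sub[cols].reset_index(drop=True)


def seed_condition_comparison(seed_maps: pd.DataFrame, band: str,
                              alpha: float = 0.05
                              ) -> Tuple[StatResult, Optional[pd.DataFrame]]:
    """Kruskal-Wallis across conditions on threshold-applied seed deltas.

    When the omnibus test is significant at ``alpha``, Bonferroni-corrected
    pairwise rank comparisons (two-group Kruskal-Wallis, equivalent to a
    tie-corrected rank-sum test) identify which conditions differ.
    """
    sub = seed_maps[seed_maps["band"] == band]
    groups = {c: g["delta"].to_numpy() for c, g in sub.groupby("condition")}
    nonempty = {c: v for c, v in groups.items() if v.size > 0}
    if len(nonempty) < 2:
        warnings.warn("fewer than two conditions with surviving entries",
                      DegenerateDataWarning)
        return StatResult(0.0, None, 1.0, degenerate=True), None
    omnibus = kruskal_wallis(list(nonempty.values()))
    if omnibus.p >= alpha:
        return omnibus, None
    conds = list(nonempty)
    m = len(conds) * (len(conds) - 1) // 2
    rows = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            res = kruskal_wallis([nonempty[conds[i]], nonempty[conds[j]]])
            rows.append({"condition_a": conds[i], "condition_b": conds[j],
                         "statistic": res.statistic, "p_raw": res.p})
    posthoc = pd.DataFrame(rows)
    posthoc["p_bonferroni"] = bonferroni_adjust(posthoc["p_raw"].to_numpy(), m)
    posthoc["family_size"] = m
    return omnibus, posthoc
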