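"""End-to-end orchestration: sessions in, tables and report out.

``run_pipeline`` executes, per subject: preprocessing, per-epoch (and
optionally pooled) pair-band MSC, baseline subtraction, regional
aggregation; then at the group level: the global condition comparison
(Friedman with pairwise post-hocs, one-sample tests against zero),
responder percentages with SNR ranking, permutation and best-frequency
statistics, hub detection, and seed-ROI maps with condition comparisons.
Every table is written as TSV with a fixed float format so reruns with the
same seed and configuration are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import coherence as coh
from . import npstats, response
from .preprocessing import apply_region_mapping, preprocess_session
from .session import (RunConfig, SessionBundle, load_region_mapping,
                      read_session)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

STAGES = ("preprocess", "coherence", "stats", "responders", "hubs", "seeds",
          "all")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def analyze_subject(bundle: SessionBundle, config: RunConfig,
                    conditions: Optional[Sequence[str]] = None) -> Dict:
    """Run the single-subject stages and return their intermediate tables."""
    config.validate()
    table = bundle.channel_table
    if config.region_mapping_path:
        table = apply_region_mapping(
            table, load_region_mapping(config.region_mapping_path))

    epochs, table, rejection = preprocess_session(
        bundle.recording, table,
        highpass_cutoff=config.highpass_cutoff,
        highpass_order=config.highpass_order,
        line_freq=config.line_freq,
        line_halfwidth=config.line_halfwidth,
        line_mad_multiplier=config.line_mad_multiplier,
        dispersion=config.dispersion,
        notch_q=config.notch_q,
        epoch_duration=config.epoch_duration,
        spike_threshold=config.spike_threshold_uv,
        target_rate=config.target_rate,
        conditions=conditions,
    )
    scheme = coh.BandScheme(dict(config.bands))
    pair_table = coh.pair_condition_table(
        epochs, scheme, window_sec=config.window_sec, overlap=config.overlap,
        taper=config.taper)
    delta_source = pair_table
    pooled = None
    if config.pooled_coherence:
        pooled = coh.pooled_pair_table(
            epochs, scheme, window_sec=config.window_sec,
            overlap=config.overlap, taper=config.taper)
        delta_source = pooled
    deltas = coh.baseline_subtract(delta_source)
    region_deltas = coh.regionize(deltas, table)
    return {
        "subject_id": bundle.recording.subject_id,
        "epochs": epochs,
        "channel_table": table,
        "rejection": rejection,
        "pair_table": pair_table,
        "pooled_table": pooled,
        "deltas": deltas,
        "region_deltas": region_deltas,
        "conditions": epochs.conditions,
    }


# ---------------------------------------------------------------------------
# Group-level statistics
# ---------------------------------------------------------------------------

def global_condition_stats(group_deltas: pd.DataFrame,
                           conditions: Sequence[str],
                           include_within_region: bool = False
                           ) -> pd.DataFrame:
    """Global distribution statistics per band (whole-brain level).

    Per band: Friedman across conditions over region pairs covered in all
    conditions; if significant, pairwise post-hoc Wilcoxon signed-rank
    (Bonferroni over the 10 unordered condition pairs); and per condition a
    one-sample Wilcoxon of the delta distribution against zero (Bonferroni
    over the 5 conditions), with r = |Z|/sqrt(N) effect sizes.
    """
    rows = []
    k = len(conditions)
    m_pairs = k * (k - 1) // 2
    for band in group_deltas["band"].unique():
        sub = group_deltas[group_deltas["band"] == band]
        if not include_within_region:
            sub = sub[sub["region_a"] != sub["region_b"]]
        wide = sub.pivot_table(index=["region_a", "region_b"],
                               columns="condition", values="delta")
        wide = wide.reindex(columns=list(conditions)).dropna()
        if len(wide) >= 2:
            fr = npstats.friedman_test(wide.to_numpy())
            rows.append({"band": band, "test": "friedman", "condition": "",
                         "condition_b": "", "statistic": fr.statistic,
                         "df": fr.df, "p": fr.p, "p_adjusted": fr.p,
                         "effect_size_r": np.nan, "n": fr.n,
                         "family_size": 1})
            if fr.p < 0.05:
                raw = []
                for i in range(k):
                    for j in range(i + 1, k):
                        w = npstats.wilcoxon_signed_rank(
                            wide[conditions[i]].to_numpy(),
                            wide[conditions[j]].to_numpy())
                        raw.append((conditions[i], conditions[j], w))
                adj = npstats.bonferroni_adjust([w.p for _, _, w in raw],
                                                m_pairs)
                for (ca, cb, w), pa in zip(raw, adj):
                    rows.append({"band": band, "test": "wilcoxon_pairwise",
                                 "condition": ca, "condition_b": cb,
                                 "statistic": w.statistic, "df": np.nan,
                                 "p": w.p, "p_adjusted": pa,
                                 "effect_size_r": w.effect_size_r, "n": w.n,
                                 "family_size": m_pairs})
        one_sample = []
        for cond in conditions:
            vals = sub.loc[sub["condition"] == cond, "delta"].to_numpy()
            if vals.size < 2:
                continue
            w = npstats.wilcoxon_signed_rank(vals, mu0=0.0)
            one_sample.append((cond, w))
        adj = npstats.bonferroni_adjust([w.p for _, w in one_sample], k)
        for (cond, w), pa in zip(one_sample, adj):
            rows.append({"band": band, "test": "wilcoxon_vs_zero",
                         "condition": cond, "condition_b": "",
                         "statistic": w.statistic, "df": np.nan, "p": w.p,
                         "p_adjusted": pa, "effect_size_r": w.effect_size_r,
                         "n": w.n, "family_size": k})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig,
                 sessions: Sequence[SessionBundle | str | Path],
                 out_dir: str | Path,
                 conditions: Optional[Sequence[str]] = None,
                 stop_after: str = "all") -> Dict:
    """Run the full analysis over one or more sessions and write results.

    ``sessions`` may be bundle objects or paths to bundle directories.
    ``stop_after`` truncates the pipeline after a named stage (the CLI's
    stage subcommands map onto it).  Returns the in-memory results dict.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    if len(sessions) == 0:
        raise ValueError("need >= 1 session")
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundles = [s if isinstance(s, SessionBundle) else read_session(s)
               for s in sessions]
    subjects = [analyze_subject(b, config, conditions=conditions)
                for b in bundles]
    cond_order = subjects[0]["conditions"]

    results: Dict = {"config": config, "subjects": subjects,
                     "conditions": cond_order}
    for sub in subjects:
        sid = sub["subject_id"]
        _write(sub["rejection"], out / f"{sid}_rejection.tsv")
        _write(sub["channel_table"], out / f"{sid}_channels.tsv")
    if stop_after == "preprocess":
        _manifest(config, out)
        return results

    for sub in subjects:
        sid = sub["subject_id"]
        _write(sub["pair_table"], out / f"{sid}_pair_band.tsv")
        if sub["pooled_table"] is not None:
            _write(sub["pooled_table"], out / f"{sid}_pair_band_pooled.tsv")
        _write(sub["deltas"], out / f"{sid}_pair_delta.tsv")
        sub["region_deltas"].insert(0, "subject", sid)
        _write(sub["region_deltas"], out / f"{sid}_region_delta.tsv")

    group_deltas = coh.group_aggregate(
        [s["region_deltas"].drop(columns="subject") for s in subjects])
    results["group_deltas"] = group_deltas
    _write(group_deltas, out / "group_region_delta.tsv")
    for band in config.bands:
        for cond in cond_order:
            mat = coh.region_matrix(group_deltas, cond, band)
            mat.to_csv(out / f"group_matrix_{cond}_{band}.tsv", sep="\t",
                       float_format=_FLOAT_FMT)
    if stop_after == "coherence":
        _manifest(config, out)
        return results

    stats_tbl = global_condition_stats(
        group_deltas, cond_order,
        include_within_region=config.include_within_region)
    results["global_stats"] = stats_tbl
    _write(stats_tbl, out / "stats_global.tsv")
    if stop_after == "stats":
        _manifest(config, out)
        return results

    # Responder percentages per subject/condition/band.
    resp_frames = []
    for sub in subjects:
        pair_d, summary = response.responder_map(
            sub["pair_table"], threshold=config.responder_threshold)
        summary.insert(0, "subject", sub["subject_id"])
        resp_frames.append(summary)
        sub["responder_pairs"] = pair_d
    responders = pd.concat(resp_frames, ignore_index=True)
    results["responders"] = responders
    _write(responders, out / "responder_summary.tsv")

    snr_rows, rank_rows = [], []
    for band in config.bands:
        bsub = responders[responders["band"] == band]
        wide = bsub.pivot_table(index="subject", columns="condition",
                                values="percentage")
        wide = wide.reindex(columns=cond_order)
        if wide.isna().any().any() or len(wide) < 2:
            logger.warning("band %s: incomplete percentage matrix; skipping "
                           "SNR/permutation/ranking", band)
            continue
        m = wide.to_numpy()
        prof = response.snr_profile(m, cond_order, sd_mode=config.sd_mode)
        pvals = response.permutation_snr_test(
            m, n_perm=config.n_perm, seed=config.rng_seed,
            mode=config.perm_mode, sd_mode=config.sd_mode)
        prof["permutation_p"] = pvals
        prof.insert(0, "band", band)
        snr_rows.append(prof)
        counts, mp = response.best_frequency_ranking(
            bsub.rename(columns={"percentage": "percentage"}), band,
            cond_order)
        rank_rows.append(pd.DataFrame({
            "band": band, "condition": list(counts),
            "n_subjects_best": list(counts.values()),
            "multinomial_p": mp}))
    snr_table = (pd.concat(snr_rows, ignore_index=True)
                 if snr_rows else pd.DataFrame())
    ranking = (pd.concat(rank_rows, ignore_index=True)
               if rank_rows else pd.DataFrame())
    results["snr"] = snr_table
    results["ranking"] = ranking
    if not snr_table.empty:
        _write(snr_table, out / "snr.tsv")
    if not ranking.empty:
        _write(ranking, out / "ranking.tsv")
    if stop_after == "responders":
        _manifest(config, out)
        return results

    hub_rows = []
    hubs = {}
    for band in config.bands:
        for cond in cond_order:
            try:
                h = response.hub_pairs(
                    group_deltas, cond, band, sd_mode=config.sd_mode,
                    include_within_region=config.include_within_region)
            except ValueError:
                continue
            hubs[(cond, band)] = h
            for a, b in h.pairs:
                hub_rows.append({"condition": cond, "band": band,
                                 "region_a": a, "region_b": b,
                                 "threshold": h.threshold,
                                 "is_hub_region_a": a in h.hub_regions,
                                 "is_hub_region_b": b in h.hub_regions})
    results["hubs"] = hubs
    _write(pd.DataFrame(hub_rows,
                        columns=["condition", "band", "region_a", "region_b",
                                 "threshold", "is_hub_region_a",
                                 "is_hub_region_b"]),
           out / "hubs.tsv")
    if stop_after == "hubs":
        _manifest(config, out)
        return results

    seed_tables = {}
    comp_rows = []
    for seed_region in config.seed_regions:
        try:
            smap = response.seed_map(group_deltas, seed_region,
                                     threshold=config.seed_map_threshold)
        except ValueError:
            logger.warning("seed region %s has no coverage", seed_region)
            continue
        seed_tables[seed_region] = smap
        _write(smap, out / f"seed_{seed_region}.tsv")
        for band in config.bands:
            omnibus, posthoc = response.seed_condition_comparison(smap, band)
            comp_rows.append({"seed": seed_region, "band": band,
                              "kruskal_h": omnibus.statistic,
                              "df": omnibus.df if omnibus.df else 0,
                              "p": omnibus.p,
                              "n": omnibus.n,
                              "posthoc_pairs": 0 if posthoc is None
                              else len(posthoc)})
            if posthoc is not None:
                posthoc.insert(0, "seed", seed_region)
                posthoc.insert(1, "band", band)
                _write(posthoc, out / f"seed_{seed_region}_{band}_posthoc.tsv")
    results["seed_maps"] = seed_tables
    seed_comp = pd.DataFrame(comp_rows)
    results["seed_comparisons"] = seed_comp
    if not seed_comp.empty:
        _write(seed_comp, out / "seed_comparison.tsv")

    report = write_report(results)
    (out / "report.txt").write_text(report)
    _manifest(config, out)
    return results


def _manifest(config: RunConfig, out: Path) -> None:
    import scipy

    from . import __version__
    manifest = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "versions": {"seegcoh": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                      sort_keys=True))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_report(results: Dict) -> str:
    """Human-readable summary of a pipeline run."""
    lines: List[str] = []
    cfg: RunConfig = results["config"]
    conds = results["conditions"]
    lines.append("Stimulation-evoked coherence analysis")
    lines.append("=" * 48)
    lines.append(f"subjects: {len(results['subjects'])}; "
                 f"conditions: {', '.join(conds)}")
    lines.append("")

    if "global_stats" in results and not results["global_stats"].empty:
        lines.append("Global condition statistics (band / test / p, "
                     "Bonferroni family size in brackets)")
        for _, r in results["global_stats"].iterrows():
            label = r["condition"]
            if r["condition_b"]:
                label += f" vs {r['condition_b']}"
            extra = ("" if pd.isna(r["effect_size_r"])
                     else f", r={r['effect_size_r']:.3f}")
            lines.append(f"  {r['band']:>6} {r['test']:<18} {label:<16} "
                         f"stat={r['statistic']:.3f} p_adj="
                         f"{r['p_adjusted']:.4g} [m={int(r['family_size'])}]"
                         f"{extra}")
        lines.append("")

    if "responders" in results:
        lines.append(f"Responder percentages (Cohen's d > "
                     f"{cfg.responder_threshold}, per subject):")
        for _, r in results["responders"].iterrows():
            lines.append(f"  {r['subject']} {r['band']:>6} "
                         f"{r['condition']:>5}: {r['percentage']:.1f}% "
                         f"({int(r['n_responders'])}/{int(r['n_pairs'])})")
        lines.append("")

    if "snr" in results and not results["snr"].empty:
        lines.append("SNR ranking (mean/SD of responder % across subjects; "
                     f"permutation mode: {cfg.perm_mode}, "
                     f"n_perm={cfg.n_perm}):")
        for _, r in results["snr"].iterrows():
            lines.append(f"  {r['band']:>6} {r['condition']:>5}: "
                         f"SNR={r['snr']:.3f} rank={int(r['rank'])} "
                         f"perm_p={r['permutation_p']:.4g}")
        lines.append("")

    if "ranking" in results and not results["ranking"].empty:
        lines.append("Best-frequency counts (exact multinomial vs uniform):")
        for band, g in results["ranking"].groupby("band"):
            counts = ", ".join(f"{r['condition']}:"
                               f"{int(r['n_subjects_best'])}"
                               for _, r in g.iterrows())
            lines.append(f"  {band:>6}: {counts}  "
                         f"p={g['multinomial_p'].iloc[0]:.4g}")
        lines.append("")

    if "hubs" in results:
        lines.append("Hub pairs (delta >= mean + 2 SD of the global "
                     f"distribution, {cfg.sd_mode} SD):")
        any_hub = False
        for (cond, band), h in results["hubs"].items():
            for a, b in h.pairs:
                any_hub = True
                mark = " *hub*" if (a in h.hub_regions
                                    or b in h.hub_regions) else ""
            if h.pairs:
                pair_str = "; ".join(f"{a}--{b}" for a, b in h.pairs)
                lines.append(f"  {band:>6} {cond:>5}: {pair_str}"
                             f" (hub regions: "
                             f"{', '.join(h.hub_regions) or 'none'})")
        if not any_hub:
            lines.append("  none")
        lines.append("")

    if "seed_maps" in results:
        lines.append(f"Seed maps (|delta| > {cfg.seed_map_threshold}):")
        if not results["seed_maps"]:
            lines.append("  none")
        for seed_region, smap in results["seed_maps"].items():
            lines.append(f"  seed {seed_region}: {len(smap)} surviving "
                         f"entries")
    return "\n".join(lines) + "\n"
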