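"""Magnitude-squared coherence (MSC) and region-pair connectivity.

The central quantity is Welch-estimated MSC,

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f)),

computed per 5-second epoch from K tapered, overlapping segments
(2.5 s windows, 70% overlap at 500 Hz give K = 4 and a 0.4 Hz grid),
averaged over canonical bands, baseline-subtracted per electrode pair, and
aggregated to anatomical region pairs at the subject and group level.

A single-segment estimate is identically 1 for any pair of signals, so the
estimator refuses K = 1.  Per-epoch estimates carry the well-known O(1/K)
upward bias for weakly coherent signals; baseline subtraction cancels it.
A pooled mode (segments from all epochs of a condition enter one estimate)
is provided where a nearly unbiased level estimate is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .preprocessing import BASELINE, EXCLUDE_CLASSES, EpochSet

logger = logging.getLogger(__name__)

#: Canonical frequency bands, half-open [low, high) Hz.  Half-open edges
#: resolve the shared 8 Hz and 13 Hz boundaries between adjacent bands.
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (70.0, 170.0),
}


@dataclass
class BandScheme:
    """Named half-open frequency intervals [low, high) in Hz."""

    bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        items = sorted(self.bands.items(), key=lambda kv: kv[1][0])
        for (na, (la, ha)), (nb, (lb, hb)) in zip(items, items[1:]):
            if hb <= lb or ha <= la:
                raise ValueError("band intervals must have low < high")
            if lb < ha and la < hb:
                raise ValueError(f"bands {na} and {nb} overlap")

    def names(self) -> List[str]:
        return list(self.bands)


@dataclass
class MscSpectrum:
    """MSC on a frequency grid, with the segment count K that produced it."""

    freqs: np.ndarray
    values: np.ndarray
    k_segments: int


class SingleSegmentError(ValueError):
    """Raised when a coherence estimate would use a single Welch segment."""


# ---------------------------------------------------------------------------
# Welch segment machinery
# ---------------------------------------------------------------------------

def _segment_params(n_samples: int, fs: float, window_sec: float,
                    overlap: float) -> Tuple[int, int, int]:
    nper = int(round(window_sec * fs))
    if nper < 2:
        raise ValueError("window too short")
    if n_samples < nper:
        raise ValueError("signal shorter than one window")
    hop = nper - int(round(overlap * nper))
    if hop < 1:
        raise ValueError("overlap too large")
    k = 1 + (n_samples - nper) // hop
    if k < 2:
        raise SingleSegmentError(
            "single-segment MSC is identically 1; shorten the window or "
            "lengthen the signal so that K >= 2")
    return nper, hop, k

_WINDOWS = ("hamming", "hann")


def _segment_ffts(x: np.ndarray, nper: int, hop: int, k: int,
                  taper: str) -> np.ndarray:
    """Detrended, tapered segment FFTs: (..., K, nfreq)."""
    if taper not in _WINDOWS:
        raise ValueError(f"taper must be one of {_WINDOWS}")
    win = _sig.get_window(taper, nper)  # periodic, the Welch convention
    idx = np.arange(nper)[None, :] + hop * np.arange(k)[:, None]
    segs = x[..., idx]                                    # (..., K, nper)
    segs = segs - segs.mean(axis=-1, keepdims=True)       # constant detrend
    return np.fft.rfft(segs * win, axis=-1)


def msc_spectrum(x: np.ndarray, y: np.ndarray, fs: float,
                 window_sec: float = 2.5, overlap: float = 0.70,
                 taper: str = "hamming") -> MscSpectrum:
    """Welch magnitude-squared coherence of two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    nper, hop, k = _segment_params(x.size, fs, window_sec, overlap)
    fx = _segment_ffts(x, nper, hop, k, taper)
    fy = _segment_ffts(y, nper, hop, k, taper)
    pxx = (fx * fx.conj()).real.mean(axis=0)
    pyy = (fy * fy.conj()).real.mean(axis=0)
    pxy = (fx * fy.conj()).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(pxy) ** 2 / (pxx * pyy)
    c = np.nan_to_num(c, nan=0.0)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    return MscSpectrum(freqs=freqs, values=np.clip(c, 0.0, 1.0), k_segments=k)


def band_msc(spectrum: MscSpectrum, scheme: Optional[BandScheme] = None
             ) -> Dict[str, float]:
    """Unweighted mean of C(f) over the bins with low <= f < high per band."""
    scheme = scheme or BandScheme()
    out = {}
    fmax = spectrum.freqs[-1]
    for name, (lo, hi) in scheme.bands.items():
        if lo >= fmax:
            raise ValueError(f"band {name} [{lo},{hi}) lies beyond the grid "
                             f"(max {fmax} Hz)")
        m = (spectrum.freqs >= lo) & (spectrum.freqs < hi)
        if not m.any():
            raise ValueError(f"band {name} contains no frequency bins")
        out[name] = float(spectrum.values[m].mean())
    return out


# ---------------------------------------------------------------------------
# All-pairs epoch tables
# ---------------------------------------------------------------------------

def _band_bin_masks(nper: int, fs: float, scheme: BandScheme
                    ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    masks = {}
    for name, (lo, hi) in scheme.bands.items():
        if lo >= fs / 2:
            raise ValueError(f"band {name} beyond Nyquist ({fs / 2} Hz)")
        m = (freqs >= lo) & (freqs < hi)
        if not m.any():
            raise ValueError(f"band {name} contains no frequency bins")
        masks[name] = m
    return freqs, masks


def _epoch_pair_band_msc(epoch: np.ndarray, fs: float, window_sec: float,
                         overlap: float, taper: str, scheme: BandScheme
                         ) -> Dict[str, np.ndarray]:
    """Band-averaged MSC for every channel pair of one epoch.

    Returns per band a (C, C) symmetric matrix.  Segment FFTs are computed
    once per channel and cross spectra formed for all pairs at once.
    """
    nper, hop, k = _segment_params(epoch.shape[-1], fs, window_sec, overlap)
    _, masks = _band_bin_masks(nper, fs, scheme)
    keep_bins = np.zeros(nper // 2 + 1, dtype=bool)
    for m in masks.values():
        keep_bins |= m
    fx = _segment_ffts(epoch, nper, hop, k, taper)[..., keep_bins]  # (C,K,F)
    pxx = (fx * fx.conj()).real.mean(axis=1)                        # (C,F)
    pxy = np.einsum("ikf,jkf->ijf", fx, fx.conj()) / k              # (C,C,F)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(pxy) ** 2 / (pxx[:, None, :] * pxx[None, :, :])
    c = np.clip(np.nan_to_num(c, nan=0.0), 0.0, 1.0)
    sub = {name: masks[name][keep_bins] for name in masks}
    return {name: c[..., m].mean(axis=-1) for name, m in sub.items()}


def pair_condition_table(epochs: EpochSet, scheme: Optional[BandScheme] = None,
                         window_sec: float = 2.5, overlap: float = 0.70,
                         taper: str = "hamming") -> pd.DataFrame:
    """Per-epoch band MSC for every unordered electrode pair and condition.

    Long-format table with columns (chan_a, chan_b, condition, epoch, band,
    msc); an epoch enters a pair's rows only when both channels' keep masks
    are true.  Conditions that lose every epoch are flagged with a warning,
    never silently zeroed.
    """
    scheme = scheme or BandScheme()
    chans = epochs.channel_ids
    n_ch = len(chans)
    if n_ch < 2:
        raise ValueError("need >= 2 channels")
    iu = np.triu_indices(n_ch, k=1)

    chan_arr = np.asarray(chans)
    cols: Dict[str, list] = {k: [] for k in
                             ("chan_a", "chan_b", "condition", "epoch",
                              "band", "msc")}
    for cond, arr in epochs.data.items():
        mask = epochs.keep[cond]
        any_epoch = False
        for e in range(arr.shape[0]):
            valid = mask[e]
            if valid.sum() < 2:
                continue
            any_epoch = True
            bands = _epoch_pair_band_msc(arr[e], epochs.fs, window_sec,
                                         overlap, taper, scheme)
            pair_ok = valid[iu[0]] & valid[iu[1]]
            n_ok = int(pair_ok.sum())
            for bname, mat in bands.items():
                cols["chan_a"].append(chan_arr[iu[0][pair_ok]])
                cols["chan_b"].append(chan_arr[iu[1][pair_ok]])
                cols["condition"].append(np.repeat(cond, n_ok))
                cols["epoch"].append(np.full(n_ok, e))
                cols["band"].append(np.repeat(bname, n_ok))
                cols["msc"].append(mat[iu][pair_ok])
        if not any_epoch:
            warnings.warn(f"condition {cond!r} has no valid epochs")
    if not cols["msc"]:
        raise ValueError("no valid epochs in any condition")
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


def pooled_pair_table(epochs: EpochSet, scheme: Optional[BandScheme] = None,
                      window_sec: float = 2.5, overlap: float = 0.70,
                      taper: str = "hamming") -> pd.DataFrame:
    """Band MSC per pair/condition pooling Welch segments across epochs.

    One estimate per (pair, condition, band) from the union of all valid
    epochs' segments (K = 4 x n_epochs at default settings), trading the
    per-epoch distribution for a nearly unbiased coherence level.  Only
    epochs valid on both channels of a pair contribute to that pair.
    """
    scheme = scheme or BandScheme()
    chans = np.asarray(epochs.channel_ids)
    n_ch = len(chans)
    if n_ch < 2:
        raise ValueError("need >= 2 channels")
    nper, hop, k = _segment_params(epochs.n_samples, epochs.fs, window_sec,
                                   overlap)
    _, masks = _band_bin_masks(nper, epochs.fs, scheme)
    keep_bins = np.zeros(nper // 2 + 1, dtype=bool)
    for m in masks.values():
        keep_bins |= m
    iu = np.triu_indices(n_ch, k=1)

    rows = []
    for cond, arr in epochs.data.items():
        mask = epochs.keep[cond]
        # Segment FFTs for every epoch: (E, C, K, F)
        fx = np.stack([
            _segment_ffts(arr[e], nper, hop, k, taper)[..., keep_bins]
            for e in range(arr.shape[0])
        ])
        # Per-pair accumulation honouring pairwise validity.
        valid = mask[:, iu[0]] & mask[:, iu[1]]          # (E, P)
        pxx_e = (fx * fx.conj()).real.sum(axis=2)        # (E, C, F)
        pxy_e = np.einsum("eikf,ejkf->eijf", fx, fx.conj())
        pxy_pairs = pxy_e[:, iu[0], iu[1], :]            # (E, P, F)
        pxx_a = pxx_e[:, iu[0], :]
        pxx_b = pxx_e[:, iu[1], :]
        w = valid[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (np.abs((pxy_pairs * w).sum(axis=0)) ** 2
                 / ((pxx_a * w).sum(axis=0) * (pxx_b * w).sum(axis=0)))
        c = np.clip(np.nan_to_num(c, nan=0.0), 0.0, 1.0)
        n_ep = valid.sum(axis=0)
        sub = {name: masks[name][keep_bins] for name in masks}
        for bname, m in sub.items():
            vals = c[:, m].mean(axis=-1)
            ok = n_ep >= 1
            rows.append(pd.DataFrame({
                "chan_a": chans[iu[0][ok]],
                "chan_b": chans[iu[1][ok]],
                "condition": cond,
                "band": bname,
                "msc": vals[ok],
                "n_epochs": n_ep[ok],
                "k_segments": n_ep[ok] * k,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Baseline subtraction and regional aggregation
# ---------------------------------------------------------------------------

def baseline_subtract(table: pd.DataFrame, baseline_label: str = BASELINE
                      ) -> pd.DataFrame:
    """Delta = mean condition MSC - mean baseline MSC per pair and band.

    Works on either the per-epoch or the pooled table (the pooled table has
    one value per condition, so the mean is that value).  Pairs without any
    baseline value are excluded and logged.
    """
    means = (table.groupby(["chan_a", "chan_b", "condition", "band"],
                           sort=False)["msc"]
             .agg(["mean", "size"]).reset_index())
    base = means[means["condition"] == baseline_label]
    stim = means[means["condition"] != baseline_label]
    merged = stim.merge(
        base[["chan_a", "chan_b", "band", "mean", "size"]],
        on=["chan_a", "chan_b", "band"], how="left",
        suffixes=("", "_base"))
    missing = merged["mean_base"].isna()
    if missing.any():
        dropped = merged.loc[missing, ["chan_a", "chan_b"]].drop_duplicates()
        logger.warning("excluding %d pair(s) with no baseline epochs",
                       len(dropped))
        merged = merged[~missing]
    merged["delta"] = merged["mean"] - merged["mean_base"]
    out = merged.rename(columns={"size": "n_stim", "size_base": "n_base"})
    return out[["chan_a", "chan_b", "condition", "band", "delta",
                "n_stim", "n_base"]].reset_index(drop=True)


def regionize(deltas: pd.DataFrame, channel_table: pd.DataFrame
              ) -> pd.DataFrame:
    """Aggregate electrode-pair deltas to region pairs (subject level).

    The region-pair delta is the mean over all electrode pairs whose two
    contacts lie in the two regions; distinct contacts within one region
    populate the diagonal.  Contacts carrying an exclusion class contribute
    nothing.
    """
    tbl = channel_table.set_index("channel_id")
    region = tbl["region"].to_dict()
    excl = set(tbl.index[tbl["exclude_class"].isin(EXCLUDE_CLASSES)])

    d = deltas[~deltas["chan_a"].isin(excl) & ~deltas["chan_b"].isin(excl)].copy()
    missing = [c for c in pd.unique(d[["chan_a", "chan_b"]].values.ravel())
               if c not in region]
    if missing:
        raise ValueError(f"channels without region label: {missing}")
    ra = d["chan_a"].map(region)
    rb = d["chan_b"].map(region)
    swap = ra > rb
    d["region_a"] = ra.where(~swap, rb)
    d["region_b"] = rb.where(~swap, ra)
    out = (d.groupby(["region_a", "region_b", "condition", "band"],
                     sort=False)["delta"]
           .agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "delta", "size": "n_pairs"}))
    return out


def group_aggregate(subject_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Group-level region-pair deltas: mean across covering subjects.

    Pairs covered by no subject are simply absent.  The result records the
    contributing-subject count and is invariant to the subject order.
    """
    if len(subject_tables) == 0:
        raise ValueError("need >= 1 subject")
    allsub = pd.concat(subject_tables, ignore_index=True)
    out = (allsub.groupby(["region_a", "region_b", "condition", "band"],
                          sort=False)["delta"]
           .agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "delta", "size": "n_subjects"}))
    return out


def region_matrix(region_deltas: pd.DataFrame, condition: str, band: str
                  ) -> pd.DataFrame:
    """Square symmetric region x region delta matrix for one condition/band."""
    sub = region_deltas[(region_deltas["condition"] == condition)
                        & (region_deltas["band"] == band)]
    regions = sorted(set(sub["region_a"]) | set(sub["region_b"]))
    mat = pd.DataFrame(np.nan, index=regions, columns=regions)
    for _, row in sub.iterrows():
        mat.loc[row["region_a"], row["region_b"]] = row["delta"]
        mat.loc[row["region_b"], row["region_a"]] = row["delta"]
    return mat


def global_distribution(region_deltas: pd.DataFrame, condition: str,
                        band: str, include_within_region: bool = False
                        ) -> np.ndarray:
    """The 'global distribution' of deltas over region pairs.

    Within-region (diagonal) entries are excluded by default; a switch
    includes them, since the intended composition cannot be pinned down.
    """
    sub = region_deltas[(region_deltas["condition"] == condition)
                        & (region_deltas["band"] == band)]
    if not include_within_region:
        sub = sub[sub["region_a"] != sub["region_b"]]
    return sub["delta"].to_numpy()
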