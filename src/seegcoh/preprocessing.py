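"""Preprocessing of raw multichannel intracranial recordings.

Turns a continuous sEEG-like recording with an event schedule into clean,
condition-labelled 5-second epochs.  The stage order is fixed:

    highpass -> line-noise channel detection/exclusion -> label-based
    exclusion -> common average reference -> 60 Hz notch -> epoching ->
    amplitude-based epoch rejection -> downsampling

All filtering is zero-phase (forward-backward), so no stage introduces a
condition-independent phase shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

BASELINE = "baseline"
EXCLUDE_CLASSES = ("white_matter", "ventricle", "unknown")


@dataclass
class Recording:
    """A continuous multichannel recording with its event schedule.

    ``samples`` is channels x time in microvolts; ``events`` has columns
    ``condition`` (label; ``"baseline"`` marks the resting segment),
    ``onset_sample`` and ``duration_samples``.
    """

    subject_id: str
    fs: float
    channel_ids: List[str]
    samples: np.ndarray
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_ids):
            raise ValueError("samples must be channels x time matching channel_ids")
        ends = self.events["onset_sample"] + self.events["duration_samples"]
        if (self.events["onset_sample"] < 0).any() or (ends > self.samples.shape[1]).any():
            raise ValueError("event extends outside the recording")


@dataclass
class EpochSet:
    """Fixed-length epochs grouped by condition with per-channel keep masks.

    ``data[cond]`` is (n_epochs, n_channels, n_samples); ``keep[cond]`` is a
    boolean (n_epochs, n_channels) mask.  All conditions share the channel
    list and the effective sampling rate.
    """

    fs: float
    channel_ids: List[str]
    data: Dict[str, np.ndarray]
    keep: Dict[str, np.ndarray] = field(default_factory=dict)
    conditions: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {arr.shape[-1] for arr in self.data.values()}
        if len(lengths) > 1:
            raise ValueError("all epochs must have the same length")
        if not self.conditions:
            self.conditions = [c for c in self.data if c != BASELINE]
        for cond, arr in self.data.items():
            if cond not in self.keep:
                self.keep[cond] = np.ones(arr.shape[:2], dtype=bool)
            if self.keep[cond].shape != arr.shape[:2]:
                raise ValueError("keep mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[-1]


def make_channel_table(channel_ids: Sequence[str], regions: Sequence[str],
                       exclude_class: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Build a channel table (channel_id, region, exclude_class, noise_flag)."""
    if exclude_class is None:
        exclude_class = [""] * len(channel_ids)
    return pd.DataFrame({
        "channel_id": list(channel_ids),
        "region": list(regions),
        "exclude_class": list(exclude_class),
        "noise_flag": [False] * len(channel_ids),
    })


def apply_region_mapping(channel_table: pd.DataFrame,
                         mapping: Dict[str, str]) -> pd.DataFrame:
    """Map raw anatomical labels onto the grouped region scheme.

    Labels absent from ``mapping`` are kept unchanged; rows whose mapped
    label is one of the exclusion classes get that exclusion class set.
    """
    out = channel_table.copy()
    mapped = out["region"].map(lambda r: mapping.get(r, r))
    out["region"] = mapped
    excl = mapped.isin(EXCLUDE_CLASSES)
    out.loc[excl, "exclude_class"] = mapped[excl]
    return out


# ---------------------------------------------------------------------------
# Filtering stages
# ---------------------------------------------------------------------------

def highpass(recording: Recording, cutoff: float = 0.5, order: int = 4) -> Recording:
    """Zero-phase Butterworth highpass, identical across channels."""
    if cutoff >= recording.fs / 2:
        raise ValueError("highpass cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff, btype="highpass", fs=recording.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=-1)
    return replace(recording, samples=filtered)


def notch(recording: Recording, freq: float = 60.0, q: float = 30.0) -> Recording:
    """Zero-phase second-order IIR notch at ``freq`` (default 60 Hz mains)."""
    if freq >= recording.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(freq, q, fs=recording.fs)
    filtered = signal.filtfilt(b, a, recording.samples, axis=-1)
    return replace(recording, samples=filtered)


def detect_line_noise_channels(recording: Recording, freq: float = 60.0,
                               halfwidth: float = 1.0,
                               mad_multiplier: float = 3.0,
                               dispersion: str = "mean_abs") -> List[str]:
    """Channels whose mains-band power is an outlier across the montage.

    Per channel, Welch PSD integrated over ``freq +- halfwidth``; a channel
    is flagged when its power exceeds the cross-channel median by more than
    ``mad_multiplier`` dispersions, where the dispersion is the mean (or
    median, configurable) absolute deviation about the median.
    """
    n_ch, n_t = recording.samples.shape
    if n_ch < 3:
        raise ValueError("robust detection needs >= 3 channels")
    if n_t < 4 * recording.fs:
        raise ValueError("recording too short for PSD-based detection")
    nperseg = int(min(4 * recording.fs, n_t))
    f, pxx = signal.welch(recording.samples, fs=recording.fs, nperseg=nperseg,
                          noverlap=0, axis=-1)
    band = (f >= freq - halfwidth) & (f <= freq + halfwidth)
    power = pxx[:, band].sum(axis=1)
    med = np.median(power)
    dev = np.abs(power - med)
    if dispersion == "mean_abs":
        spread = dev.mean()
    elif dispersion == "median_abs":
        spread = np.median(dev)
    else:
        raise ValueError("dispersion must be 'mean_abs' or 'median_abs'")
    flagged = power > med + mad_multiplier * spread
    return [recording.channel_ids[i] for i in np.nonzero(flagged)[0]]


def apply_car(recording: Recording, kept_channels: Sequence[str]) -> Recording:
    """Common average reference over ``kept_channels``; others are dropped."""
    kept = [c for c in recording.channel_ids if c in set(kept_channels)]
    if len(kept) < 2:
        raise ValueError("CAR needs >= 2 kept channels")
    idx = [recording.channel_ids.index(c) for c in kept]
    sub = recording.samples[idx]
    referenced = sub - sub.mean(axis=0, keepdims=True)
    return replace(recording, channel_ids=kept, samples=referenced)


# ---------------------------------------------------------------------------
# Epoching, rejection, downsampling
# ---------------------------------------------------------------------------

def epoch_session(recording: Recording, epoch_duration: float = 5.0,
                  conditions: Optional[Sequence[str]] = None) -> EpochSet:
    """Cut the recording into fixed-length condition-labelled epochs.

    The baseline segment is split into consecutive non-overlapping epochs;
    each stimulation event yields exactly one epoch under its condition
    label.  Off-period data between events is discarded.
    """
    n_per = int(round(epoch_duration * recording.fs))
    ev = recording.events
    base = ev[ev["condition"] == BASELINE]
    stim = ev[ev["condition"] != BASELINE]

    data: Dict[str, List[np.ndarray]] = {}
    base_epochs: List[np.ndarray] = []
    for _, row in base.iterrows():
        n_full = int(row["duration_samples"]) // n_per
        for i in range(n_full):
            s0 = int(row["onset_sample"]) + i * n_per
            base_epochs.append(recording.samples[:, s0:s0 + n_per])
    if not base_epochs:
        raise ValueError("no usable baseline epochs")
    data[BASELINE] = base_epochs

    order: List[str] = list(conditions) if conditions is not None else []
    for _, row in stim.iterrows():
        cond = row["condition"]
        s0 = int(row["onset_sample"])
        if s0 + n_per > recording.samples.shape[1]:
            raise ValueError(f"event at sample {s0} extends past recording end")
        if cond not in order:
            order.append(cond)
        data.setdefault(cond, []).append(recording.samples[:, s0:s0 + n_per])

    stacked = {c: np.stack(eps) for c, eps in data.items()}
    return EpochSet(fs=recording.fs, channel_ids=list(recording.channel_ids),
                    data=stacked, conditions=order)


def reject_spike_epochs(epochs: EpochSet, threshold: float = 500.0
                        ) -> Tuple[EpochSet, pd.DataFrame]:
    """Flag channel-epochs containing large transients.

    A (channel, epoch) slot is rejected iff max |sample| strictly exceeds
    ``threshold`` (microvolts); a peak exactly at the threshold is kept.
    Returns the masked EpochSet and a per-channel rejection-proportion
    summary.
    """
    new_keep = {}
    rows = []
    for cond, arr in epochs.data.items():
        peaks = np.abs(arr).max(axis=-1)           # epochs x channels
        ok = peaks <= threshold
        new_keep[cond] = epochs.keep[cond] & ok
        for ci, ch in enumerate(epochs.channel_ids):
            rows.append({
                "condition": cond,
                "channel_id": ch,
                "n_epochs": arr.shape[0],
                "n_rejected": int((~ok[:, ci]).sum()),
            })
    summary = pd.DataFrame(rows)
    summary["proportion_rejected"] = summary["n_rejected"] / summary["n_epochs"]
    if any(not m.any() for m in new_keep.values()):
        warnings.warn("a condition lost every epoch on every channel")
    out = EpochSet(fs=epochs.fs, channel_ids=list(epochs.channel_ids),
                   data=dict(epochs.data), keep=new_keep,
                   conditions=list(epochs.conditions))
    return out, summary


def downsample(epochs: EpochSet, target: float = 500.0) -> EpochSet:
    """Anti-alias filter and decimate each epoch to ``target`` Hz.

    The native rate must be an integer multiple of the target.  Decimation
    uses the zero-phase order-8 Chebyshev-I lowpass at 0.8x the new Nyquist.
    """
    factor = epochs.fs / target
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("native rate must be an integer multiple of target")
    q = int(round(factor))
    if q == 1:
        return epochs
    new_data = {c: signal.decimate(arr, q, axis=-1, zero_phase=True)
                for c, arr in epochs.data.items()}
    return EpochSet(fs=target, channel_ids=list(epochs.channel_ids),
                    data=new_data, keep={c: m.copy() for c, m in epochs.keep.items()},
                    conditions=list(epochs.conditions))


# ---------------------------------------------------------------------------
# Full stage pipeline
# ---------------------------------------------------------------------------

def preprocess_session(
    recording: Recording,
    channel_table: pd.DataFrame,
    highpass_cutoff: float = 0.5,
    highpass_order: int = 4,
    line_freq: float = 60.0,
    line_halfwidth: float = 1.0,
    line_mad_multiplier: float = 3.0,
    dispersion: str = "mean_abs",
    notch_q: float = 30.0,
    epoch_duration: float = 5.0,
    spike_threshold: float = 500.0,
    target_rate: float = 500.0,
    conditions: Optional[Sequence[str]] = None,
) -> Tuple[EpochSet, pd.DataFrame, pd.DataFrame]:
    """Run the full preprocessing chain on one session.

    Returns the clean downsampled EpochSet, the channel table with noise
    flags filled in, and the spike-rejection summary.  Line-noise detection
    runs before re-referencing so noisy channels cannot contaminate the
    common average.
    """
    rec = highpass(recording, cutoff=highpass_cutoff, order=highpass_order)

    noisy = set(detect_line_noise_channels(
        rec, freq=line_freq, halfwidth=line_halfwidth,
        mad_multiplier=line_mad_multiplier, dispersion=dispersion))
    table = channel_table.copy()
    table["noise_flag"] = table["channel_id"].isin(noisy)

    excluded_labels = table["exclude_class"].isin(EXCLUDE_CLASSES)
    keep_mask = ~table["noise_flag"] & ~excluded_labels
    kept = [c for c in rec.channel_ids
            if c in set(table.loc[keep_mask, "channel_id"])]

    rec = apply_car(rec, kept)
    rec = notch(rec, freq=line_freq, q=notch_q)
    epochs = epoch_session(rec, epoch_duration=epoch_duration,
                           conditions=conditions)
    epochs, rejection = reject_spike_epochs(epochs, threshold=spike_threshold)
    epochs = downsample(epochs, target=target_rate)
    return epochs, table, rejection
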