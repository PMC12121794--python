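"""Synthetic sEEG-like sessions with known ground-truth coherence structure.

Emulates the study design the pipeline targets: a resting baseline followed
by randomized 5-second vibration trials (five conditions, 30 trials each by
default) interleaved with 5-second off periods.  Each channel carries
1/f^alpha Gaussian background noise plus a weak within-region shared source;
designated region pairs receive a band-limited common source, gated by a
designated condition, whose expected in-band coherence follows in closed
form.  Line-noise and large-transient artifacts are injectable so the
rejection stages have an exact ground truth.

For x = a*s + n1 and y = a*s + n2 with s unit-variance band-limited noise
and n1, n2 independent with in-band power sigma_n^2, the in-band
magnitude-squared coherence is

    C = (a^2 sigma_s^2 / (a^2 sigma_s^2 + sigma_n^2))^2.

The generator records this value per injected coupling so parameter-recovery
tests have an analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import BASELINE, Recording, make_channel_table

DEFAULT_CONDITIONS = ("2Hz", "6Hz", "12Hz", "20Hz", "40Hz")


@dataclass
class CouplingSpec:
    """A band-limited common source shared by two regions under one condition.

    ``gain`` (a) scales the unit-variance source; ``source_power`` is
    sigma_s^2 in microvolt^2.  The effective added power is
    gain^2 * source_power on every channel of both regions, during ON
    epochs of ``condition`` only ("baseline" couples the resting segment).
    """

    region_a: str
    region_b: str
    band: Tuple[float, float]
    condition: str
    gain: float = 1.0
    source_power: float = 1.0

    def validate(self, nyquist: float) -> None:
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        lo, hi = self.band
        if not (0 < lo < hi <= nyquist):
            raise ValueError(f"band {self.band} must lie within (0, {nyquist}]")


@dataclass
class SpikeEvent:
    """One injected large transient: which channel, which epoch, how big."""

    channel_id: str
    epoch_index: int
    amplitude_uv: float
    epoch_type: str = "trial"      # "trial" or "baseline"
    width_ms: float = 40.0


@dataclass
class ArtifactSpec:
    """Line-noise contamination and interictal-spike-like transients.

    ``line_noise`` maps channel id -> 60 Hz amplitude in microvolts.
    """

    line_noise: Dict[str, float] = field(default_factory=dict)
    spikes: List[SpikeEvent] = field(default_factory=list)


@dataclass
class SynthConfig:
    """Full description of one synthetic session.

    Defaults reproduce the study conditions: 2 kHz sampling, 3 min baseline,
    5 s trials alternating with 5 s off, 30 trials for each of five vibration
    frequencies.  ``regions`` maps region label -> channel count.
    """

    sampling_rate: float = 2000.0
    baseline_duration: float = 180.0
    trial_duration: float = 5.0
    off_duration: float = 5.0
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS
    trials_per_condition: int = 30
    regions: Dict[str, int] = field(
        default_factory=lambda: {"L-Amyg": 4, "L-Hipp": 4, "L-OFC": 4,
                                 "L-ACC": 4, "L-Temp": 4})
    couplings: List[CouplingSpec] = field(default_factory=list)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    noise_exponent: float = 1.0
    noise_power: float = 2500.0        # microvolt^2 (50 uV RMS background)
    shared_source_gain: float = 0.3    # within-region source, relative
    lowfreq_floor: float = 1.0         # Hz below which the 1/f shape flattens
    rng_seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.trials_per_condition < 1:
            raise ValueError("invalid rate or trial count")
        if not self.regions or any(n < 1 for n in self.regions.values()):
            raise ValueError("regions must map labels to positive channel counts")
        nyq = self.sampling_rate / 2
        for spec in self.couplings:
            spec.validate(nyq)
            for r in (spec.region_a, spec.region_b):
                if r not in self.regions:
                    raise ValueError(f"coupling references unknown region {r!r}")
            if spec.condition != BASELINE and spec.condition not in self.conditions:
                raise ValueError(f"coupling references unknown condition "
                                 f"{spec.condition!r}")

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    @property
    def total_samples(self) -> int:
        dur = (self.baseline_duration
               + self.n_trials * (self.trial_duration + self.off_duration))
        return int(round(dur * self.sampling_rate))

    def channel_ids(self) -> List[str]:
        return [f"{region}_{i:02d}" for region, n in self.regions.items()
                for i in range(n)]


def config_from_dict(raw: dict) -> "SynthConfig":
    """Build a SynthConfig from a plain (e.g. YAML-loaded) mapping."""
    raw = dict(raw)
    if "conditions" in raw:
        raw["conditions"] = tuple(raw["conditions"])
    if "couplings" in raw:
        raw["couplings"] = [
            CouplingSpec(**{**c, "band": tuple(c["band"])})
            for c in raw["couplings"]]
    if "artifacts" in raw:
        art = dict(raw["artifacts"])
        art["spikes"] = [SpikeEvent(**s) for s in art.get("spikes", [])]
        art.setdefault("line_noise", {})
        raw["artifacts"] = ArtifactSpec(**art)
    cfg = SynthConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """What was actually injected: schedule, couplings, artifacts."""

    schedule: pd.DataFrame          # trial, condition, onset_sample
    couplings: pd.DataFrame         # spec fields + expected_band_msc
    artifact_log: pd.DataFrame      # kind, channel_id, detail columns
    config: SynthConfig


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def expected_band_msc(gain: float, source_power: float,
                      noise_power: float) -> float:
    """Closed-form in-band MSC of a shared-source pair (see module docs)."""
    if noise_power <= 0:
        raise ValueError("noise power must be positive")
    snr = gain * gain * source_power
    return (snr / (snr + noise_power)) ** 2


def inband_noise_power(config: SynthConfig, band: Tuple[float, float]) -> float:
    """Expected background power per channel inside ``band``.

    From the spectral weights the generator itself applies: the 1/f^alpha
    shape (flattened below ``lowfreq_floor``), scaled to ``noise_power``
    total, plus the within-region shared source of the same shape at
    ``shared_source_gain`` relative amplitude.
    """
    n = config.total_samples
    f = np.fft.rfftfreq(n, 1.0 / config.sampling_rate)
    w2 = _shape_weights(f, config.noise_exponent, config.lowfreq_floor) ** 2
    m = (f >= band[0]) & (f < band[1])
    frac = float(w2[m].sum() / w2[1:].sum())
    return config.noise_power * frac * (1.0 + config.shared_source_gain ** 2)


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _shape_weights(freqs: np.ndarray, alpha: float, floor_hz: float
                   ) -> np.ndarray:
    w = np.zeros_like(freqs)
    pos = freqs > 0
    w[pos] = np.maximum(freqs[pos], floor_hz) ** (-alpha / 2.0)
    return w


def _one_over_f_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                      fs: float, alpha: float, floor_hz: float) -> np.ndarray:
    """Rows of unit-variance 1/f^alpha Gaussian noise (frequency shaping)."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spec *= _shape_weights(f, alpha, floor_hz)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def band_limited_noise(rng: np.random.Generator, n_samples: int, fs: float,
                       band: Tuple[float, float]) -> np.ndarray:
    """Unit-variance noise with a spectrally flat brick-wall band [lo, hi).

    Built by frequency-domain masking of white noise, so the source power
    density is exactly flat inside the band and zero outside; that keeps the
    injected in-band signal-to-noise ratio, and hence the closed-form
    expected coherence, uniform across the analysis band.
    """
    lo, hi = band
    if hi > fs / 2:
        raise ValueError("band above Nyquist")
    spec = np.fft.rfft(rng.standard_normal(n_samples))
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spec[(f < lo) | (f >= hi)] = 0.0
    s = np.fft.irfft(spec, n=n_samples)
    return s / s.std()


def _spike_shape(width_samples: int) -> np.ndarray:
    """Biphasic raised-cosine transient, normalized to unit peak."""
    u = np.linspace(0.0, 1.0, width_samples)
    g = np.sin(2 * np.pi * u) * 0.5 * (1 - np.cos(2 * np.pi * u))
    return g / np.abs(g).max()


# ---------------------------------------------------------------------------
# Injection operations
# ---------------------------------------------------------------------------

def inject_coupling(signals: np.ndarray, spec: CouplingSpec,
                    on_epochs: Sequence[Tuple[int, int]],
                    fs: float, rows_a: Sequence[int], rows_b: Sequence[int],
                    rng: np.random.Generator) -> np.ndarray:
    """Add the shared band-limited source to both regions during ON epochs.

    Each ON epoch gets an independent unit-variance source realization s;
    all channels of both regions receive gain * sqrt(source_power) * s.
    Samples outside ``on_epochs`` are untouched; zero gain is a no-op.
    """
    spec.validate(fs / 2)
    out = signals
    if spec.gain == 0:
        return out
    amp = spec.gain * math.sqrt(spec.source_power)
    rows = list(rows_a) + list(rows_b)
    n_total = signals.shape[1]
    for start, stop in on_epochs:
        if not (0 <= start < stop <= n_total):
            raise ValueError("ON epoch outside recording")
        s = band_limited_noise(rng, stop - start, fs, spec.band)
        out[rows, start:stop] += amp * s
    return out


def inject_artifacts(signals: np.ndarray, spec: ArtifactSpec,
                     channel_ids: Sequence[str], fs: float,
                     epoch_slices: Dict[Tuple[str, int], Tuple[int, int]],
                     rng: np.random.Generator
                     ) -> Tuple[np.ndarray, pd.DataFrame]:
    """Add line noise and spike transients; return the injection log.

    ``epoch_slices`` maps (epoch_type, epoch_index) -> (start, stop) sample
    ranges so spikes land in well-defined analysis epochs.
    """
    index = {c: i for i, c in enumerate(channel_ids)}
    t = np.arange(signals.shape[1]) / fs
    log = []
    for ch, amp in spec.line_noise.items():
        if ch not in index:
            raise ValueError(f"unknown channel {ch!r}")
        phase = rng.uniform(0, 2 * np.pi)
        signals[index[ch]] += amp * np.sin(2 * np.pi * 60.0 * t + phase)
        log.append({"kind": "line_noise", "channel_id": ch,
                    "epoch_type": "", "epoch_index": -1,
                    "amplitude_uv": amp})
    for ev in spec.spikes:
        if ev.channel_id not in index:
            raise ValueError(f"unknown channel {ev.channel_id!r}")
        key = (ev.epoch_type, ev.epoch_index)
        if key not in epoch_slices:
            raise ValueError(f"epoch {key} out of range")
        start, stop = epoch_slices[key]
        width = int(round(ev.width_ms / 1000.0 * fs))
        center = (start + stop) // 2
        s0 = center - width // 2
        shape = _spike_shape(width) * ev.amplitude_uv
        signals[index[ev.channel_id], s0:s0 + width] += shape
        log.append({"kind": "spike", "channel_id": ev.channel_id,
                    "epoch_type": ev.epoch_type, "epoch_index": ev.epoch_index,
                    "amplitude_uv": ev.amplitude_uv})
    return signals, pd.DataFrame(
        log, columns=["kind", "channel_id", "epoch_type", "epoch_index",
                      "amplitude_uv"])


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def build_session(config: SynthConfig) -> Tuple[Recording, pd.DataFrame,
                                                GroundTruth]:
    """Generate one full session: recording, channel table, ground truth.

    The trial schedule is a seeded random permutation with exactly
    ``trials_per_condition`` occurrences of each condition.  Identical
    seeds yield bit-identical signal matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    fs = config.sampling_rate
    chan_ids = config.channel_ids()
    n_ch = len(chan_ids)
    n_total = config.total_samples

    # Randomized schedule: a permutation of 30 repeats of each condition.
    labels = np.repeat(np.array(config.conditions, dtype=object),
                       config.trials_per_condition)
    schedule_labels = rng.permutation(labels)
    base_samples = int(round(config.baseline_duration * fs))
    trial_samples = int(round(config.trial_duration * fs))
    off_samples = int(round(config.off_duration * fs))
    onsets = base_samples + np.arange(config.n_trials) * (trial_samples
                                                          + off_samples)
    schedule = pd.DataFrame({"trial": np.arange(config.n_trials),
                             "condition": schedule_labels,
                             "onset_sample": onsets})

    # Background: per-channel 1/f^alpha plus a weak per-region shared source.
    sigma = math.sqrt(config.noise_power)
    signals = sigma * _one_over_f_noise(rng, n_ch, n_total, fs,
                                        config.noise_exponent,
                                        config.lowfreq_floor)
    row = 0
    region_rows: Dict[str, List[int]] = {}
    for region, n in config.regions.items():
        region_rows[region] = list(range(row, row + n))
        row += n
    for region, rows in region_rows.items():
        shared = _one_over_f_noise(rng, 1, n_total, fs,
                                   config.noise_exponent,
                                   config.lowfreq_floor)[0]
        signals[rows] += config.shared_source_gain * sigma * shared

    # Epoch slicing shared by couplings and artifacts.
    n_base_epochs = base_samples // trial_samples
    epoch_slices: Dict[Tuple[str, int], Tuple[int, int]] = {}
    for j in range(n_base_epochs):
        epoch_slices[("baseline", j)] = (j * trial_samples,
                                         (j + 1) * trial_samples)
    for i, onset in enumerate(onsets):
        epoch_slices[("trial", i)] = (int(onset), int(onset) + trial_samples)

    # Couplings: only during ON epochs of the designated condition.
    coupling_rows = []
    for spec in config.couplings:
        if spec.condition == BASELINE:
            on = [epoch_slices[("baseline", j)] for j in range(n_base_epochs)]
        else:
            trials = schedule.loc[schedule["condition"] == spec.condition,
                                  "trial"]
            on = [epoch_slices[("trial", int(i))] for i in trials]
        signals = inject_coupling(signals, spec, on, fs,
                                  region_rows[spec.region_a],
                                  region_rows[spec.region_b], rng)
        sn = inband_noise_power(config, spec.band)
        coupling_rows.append({
            "region_a": spec.region_a, "region_b": spec.region_b,
            "band_lo": spec.band[0], "band_hi": spec.band[1],
            "condition": spec.condition, "gain": spec.gain,
            "source_power": spec.source_power,
            "inband_noise_power": sn,
            "expected_band_msc": expected_band_msc(spec.gain,
                                                   spec.source_power, sn),
        })

    signals, artifact_log = inject_artifacts(
        signals, config.artifacts, chan_ids, fs, epoch_slices, rng)

    events = pd.concat([
        pd.DataFrame({"condition": [BASELINE], "onset_sample": [0],
                      "duration_samples": [base_samples]}),
        pd.DataFrame({"condition": schedule["condition"],
                      "onset_sample": schedule["onset_sample"],
                      "duration_samples": trial_samples}),
    ], ignore_index=True)

    recording = Recording(subject_id=f"synth-{config.rng_seed}", fs=fs,
                          channel_ids=chan_ids, samples=signals,
                          events=events)
    regions = [r for r, n in config.regions.items() for _ in range(n)]
    channel_table = make_channel_table(chan_ids, regions)
    truth = GroundTruth(schedule=schedule,
                        couplings=pd.DataFrame(coupling_rows),
                        artifact_log=artifact_log, config=config)
    return recording, channel_table, truth
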