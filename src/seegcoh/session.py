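"""Session bundle I/O and run configuration.

A session bundle on disk is a directory holding:

* ``signals.bin`` -- little-endian float32, channel-major (or ``signals.edf``,
  read through MNE when available);
* ``meta.yaml``   -- subject id, sampling rate, channel ids, sample count;
* ``events.tsv``  -- condition, onset_sample, duration_samples;
* ``channels.tsv`` -- channel_id, region, exclude_class.

All tabular results elsewhere in the package are written as TSV so every
artifact stays human-readable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .preprocessing import Recording
from .synthetic import GroundTruth

#: Seed regions of interest (left-hemisphere limbic set).
DEFAULT_SEED_REGIONS = ("L-OFC", "L-ACC", "L-Amyg", "L-Hipp", "L-PHG")


@dataclass
class SessionBundle:
    """One subject's recording plus its channel/region table."""

    recording: Recording
    channel_table: pd.DataFrame


@dataclass
class RunConfig:
    """Every tunable of the analysis; defaults are the published protocol.

    Preprocessing: 0.5 Hz fourth-order highpass, 60 Hz line-noise channel
    screen (3 mean absolute deviations above the median), CAR, Q=30 notch,
    5-s epochs, 500 uV spike rejection, 500 Hz target rate.  Coherence:
    2.5 s Hamming windows at 70% overlap over theta/alpha/beta/gamma bands.
    Statistics: d > 0.2 responder rule, 10,000 permutations.
    """

    highpass_cutoff: float = 0.5
    highpass_order: int = 4
    line_freq: float = 60.0
    line_halfwidth: float = 1.0
    line_mad_multiplier: float = 3.0
    dispersion: str = "mean_abs"
    notch_q: float = 30.0
    epoch_duration: float = 5.0
    spike_threshold_uv: float = 500.0
    target_rate: float = 500.0
    window_sec: float = 2.5
    overlap: float = 0.70
    taper: str = "hamming"
    bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"theta": (4.0, 8.0), "alpha": (8.0, 13.0),
                                 "beta": (13.0, 30.0), "gamma": (70.0, 170.0)})
    responder_threshold: float = 0.2
    seed_regions: Tuple[str, ...] = DEFAULT_SEED_REGIONS
    seed_map_threshold: float = 0.01
    n_perm: int = 10000
    perm_mode: str = "strict"
    sd_mode: str = "sample"
    pooled_coherence: bool = False
    include_within_region: bool = False
    region_mapping_path: Optional[str] = None
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.overlap < 1):
            raise ValueError("overlap must be in (0, 1)")
        if self.perm_mode not in ("strict", "geq", "add_one"):
            raise ValueError("perm_mode must be 'strict', 'geq' or 'add_one'")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")
        if self.spike_threshold_uv <= 0 or self.n_perm < 1:
            raise ValueError("invalid threshold or permutation count")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        if "seed_regions" in raw:
            raw["seed_regions"] = tuple(raw["seed_regions"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["bands"] = {k: list(v) for k, v in data["bands"].items()}
        data["seed_regions"] = list(data["seed_regions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["bands"] = {k: list(v) for k, v in data["bands"].items()}
        data["seed_regions"] = list(data["seed_regions"])
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Bundle read/write
# ---------------------------------------------------------------------------

def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a session bundle directory (float32 binary + TSV + YAML)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = bundle.recording
    sig = np.ascontiguousarray(rec.samples, dtype="<f4")
    sig.tofile(path / "signals.bin")
    meta = {"subject_id": rec.subject_id, "sampling_rate": float(rec.fs),
            "channel_ids": list(rec.channel_ids),
            "n_samples": int(rec.samples.shape[1]),
            "dtype": "<f4", "order": "channel_major"}
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    rec.events.to_csv(path / "events.tsv", sep="\t", index=False)
    bundle.channel_table.to_csv(path / "channels.tsv", sep="\t", index=False)


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session bundle directory."""
    path = Path(path)
    meta_path = path / "meta.yaml"
    events_path = path / "events.tsv"
    channels_path = path / "channels.tsv"
    for p in (events_path, channels_path):
        if not p.exists():
            raise FileNotFoundError(f"missing bundle part: {p}")

    events = pd.read_csv(events_path, sep="\t")
    for col in ("condition", "onset_sample", "duration_samples"):
        if col not in events.columns:
            raise ValueError(f"events.tsv lacks column {col!r}")
    channel_table = pd.read_csv(channels_path, sep="\t",
                                keep_default_na=False)
    if "channel_id" not in channel_table.columns:
        raise ValueError("channels.tsv lacks column 'channel_id'")
    if "exclude_class" not in channel_table.columns:
        channel_table["exclude_class"] = ""
    if "noise_flag" not in channel_table.columns:
        channel_table["noise_flag"] = False

    edf_path = path / "signals.edf"
    if (path / "signals.bin").exists():
        if not meta_path.exists():
            raise FileNotFoundError(f"missing bundle part: {meta_path}")
        meta = yaml.safe_load(meta_path.read_text())
        for key in ("subject_id", "sampling_rate", "channel_ids", "n_samples"):
            if key not in meta:
                raise ValueError(f"meta.yaml lacks field {key!r}")
        n_ch = len(meta["channel_ids"])
        sig = np.fromfile(path / "signals.bin", dtype="<f4")
        if sig.size != n_ch * meta["n_samples"]:
            raise ValueError(
                f"signals.bin holds {sig.size} values, expected "
                f"{n_ch} x {meta['n_samples']}")
        samples = sig.reshape(n_ch, meta["n_samples"]).astype(float)
        subject_id = str(meta["subject_id"])
        fs = float(meta["sampling_rate"])
        channel_ids = [str(c) for c in meta["channel_ids"]]
    elif edf_path.exists():
        subject_id, fs, channel_ids, samples = _read_edf(edf_path)
    else:
        raise FileNotFoundError(f"no signals.bin or signals.edf under {path}")

    if set(channel_table["channel_id"].astype(str)) != set(channel_ids):
        raise ValueError("channels.tsv does not match the signal channel ids")
    rec = Recording(subject_id=subject_id, fs=fs, channel_ids=channel_ids,
                    samples=samples, events=events)
    return SessionBundle(recording=rec, channel_table=channel_table)


def _read_edf(path: Path) -> Tuple[str, float, List[str], np.ndarray]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' "
                          "dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # MNE stores EEG in volts; bundle convention is microvolts.
    return (path.stem, float(raw.info["sfreq"]), list(raw.ch_names),
            raw.get_data() * 1e6)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist ground truth as TSV tables plus a YAML header."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.schedule.to_csv(path / "schedule.tsv", sep="\t", index=False)
    truth.couplings.to_csv(path / "couplings.tsv", sep="\t", index=False)
    truth.artifact_log.to_csv(path / "artifacts.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(truth.config)
    cfg["conditions"] = list(cfg["conditions"])
    cfg["couplings"] = [dict(c, band=list(c["band"]))
                        for c in cfg["couplings"]]
    cfg["artifacts"]["spikes"] = [dict(s) for s in cfg["artifacts"]["spikes"]]
    (path / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_region_mapping(path: str | Path) -> Dict[str, str]:
    """Read a two-column TSV mapping raw anatomical labels to regions."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("region mapping needs two columns: label, region")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
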