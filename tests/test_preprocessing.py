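"""Filtering, channel screening, epoching, rejection, downsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

import seegcoh as sc
from seegcoh.preprocessing import (EpochSet, Recording, apply_car,
                                   detect_line_noise_channels, downsample,
                                   epoch_session, highpass, notch,
                                   preprocess_session, reject_spike_epochs)


def _recording(samples, fs=2000.0, events=None, subject="s1"):
    n_ch = samples.shape[0]
    if events is None:
        events = pd.DataFrame({"condition": ["baseline"],
                               "onset_sample": [0],
                               "duration_samples": [samples.shape[1]]})
    return Recording(subject_id=subject, fs=fs,
                     channel_ids=[f"c{i}" for i in range(n_ch)],
                     samples=samples, events=events)


def _sine(freq, fs, dur, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _mid_amplitude(x, fs, trim_sec=5.0):
    m = int(trim_sec * fs)
    return np.abs(x[m:-m]).max()


class TestHighpass:
    def test_dc_fully_rejected(self):
        rec = _recording(np.full((2, 40000), 100.0))
        out = highpass(rec)
        mid = out.samples[:, 4000:-4000]
        assert np.abs(mid).mean() < 1e-6

    def test_subcutoff_sine_strongly_attenuated(self):
        # |H|^2 at 0.1 Hz for a 4th-order 0.5 Hz Butterworth applied
        # forward-backward: (1 + (0.5/0.1)^8)^-1 = 2.56e-6 < 1e-4
        fs = 200.0
        rec = _recording(_sine(0.1, fs, 120)[None, :].repeat(2, 0), fs=fs)
        out = highpass(rec)
        assert _mid_amplitude(out.samples[0], fs, 30) < 1e-4

    def test_passband_sine_preserved(self):
        fs = 200.0
        rec = _recording(_sine(10.0, fs, 60)[None, :].repeat(2, 0), fs=fs)
        out = highpass(rec)
        m = int(5 * fs)
        gain = (np.sqrt((out.samples[0, m:-m] ** 2).mean())
                / np.sqrt((rec.samples[0, m:-m] ** 2).mean()))
        assert gain == pytest.approx(1.0, rel=1e-3)

    def test_cutoff_at_nyquist_rejected(self):
        rec = _recording(np.zeros((2, 1000)), fs=100.0)
        with pytest.raises(ValueError):
            highpass(rec, cutoff=50.0)

    def test_channelwise_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 8000))
        fs = 500.0
        fa = highpass(_recording(a[None, :], fs=fs)).samples[0]
        fb = highpass(_recording(b[None, :], fs=fs)).samples[0]
        fab = highpass(_recording((a + b)[None, :], fs=fs)).samples[0]
        assert np.allclose(fab, fa + fb, atol=1e-9)


class TestLineNoiseDetection:
    def test_identical_channels_give_empty_set(self):
        x = np.random.default_rng(1).standard_normal(20000)
        rec = _recording(np.tile(x, (5, 1)), fs=2000.0)
        assert detect_line_noise_channels(rec) == []

    def test_contaminated_channel_flagged(self):
        rng = np.random.default_rng(2)
        fs = 2000.0
        samples = rng.standard_normal((20, 40000))
        samples[7] += _sine(60.0, fs, 20, amp=10.0)
        rec = _recording(samples, fs=fs)
        assert detect_line_noise_channels(rec) == ["c7"]

    def test_ground_truth_channels_recovered(self):
        # contamination must stay a minority for the robust screen to work
        cfg = sc.SynthConfig(
            sampling_rate=500.0, baseline_duration=30.0,
            trials_per_condition=2,
            regions={"L-Amyg": 5, "L-Hipp": 5, "L-OFC": 5, "L-ACC": 5},
            artifacts=sc.ArtifactSpec(line_noise={"L-Hipp_01": 500.0,
                                                  "L-OFC_00": 500.0}),
            rng_seed=13)
        recording, _, truth = sc.build_session(cfg)
        rec = highpass(recording)
        flagged = set(detect_line_noise_channels(rec))
        assert flagged == {"L-Hipp_01", "L-OFC_00"}

    def test_too_few_channels_rejected(self):
        rec = _recording(np.random.default_rng(3).standard_normal((2, 20000)))
        with pytest.raises(ValueError):
            detect_line_noise_channels(rec)


class TestCar:
    def test_identical_channels_zeroed(self):
        x = np.random.default_rng(4).standard_normal(1000)
        rec = _recording(np.tile(x, (4, 1)), fs=500.0)
        out = apply_car(rec, rec.channel_ids)
        assert np.allclose(out.samples, 0.0)

    def test_balanced_channels_unchanged(self):
        rec = _recording(np.vstack([np.ones(100), -np.ones(100)]), fs=50.0)
        out = apply_car(rec, ["c0", "c1"])
        assert np.allclose(out.samples[0], 1.0)
        assert np.allclose(out.samples[1], -1.0)

    def test_output_mean_is_zero_and_idempotent(self):
        rng = np.random.default_rng(5)
        rec = _recording(rng.standard_normal((6, 2000)), fs=500.0)
        once = apply_car(rec, rec.channel_ids)
        assert np.abs(once.samples.mean(axis=0)).max() < 1e-12
        twice = apply_car(once, once.channel_ids)
        assert np.allclose(once.samples, twice.samples)

    def test_excluded_channels_dropped(self):
        rng = np.random.default_rng(6)
        rec = _recording(rng.standard_normal((4, 500)), fs=100.0)
        out = apply_car(rec, ["c0", "c2"])
        assert out.channel_ids == ["c0", "c2"]
        assert out.samples.shape[0] == 2

    def test_fewer_than_two_rejected(self):
        rec = _recording(np.zeros((3, 100)), fs=100.0)
        with pytest.raises(ValueError):
            apply_car(rec, ["c0"])


class TestNotch:
    def test_mains_sine_removed(self):
        fs = 2000.0
        rec = _recording(_sine(60.0, fs, 30)[None, :], fs=fs)
        out = notch(rec)
        mid = out.samples[0, 10000:-10000]
        ref = rec.samples[0, 10000:-10000]
        assert np.sqrt((mid ** 2).mean()) < 0.01 * np.sqrt((ref ** 2).mean())

    def test_off_notch_sine_preserved(self):
        fs = 2000.0
        rec = _recording(_sine(10.0, fs, 30)[None, :], fs=fs)
        out = notch(rec)
        assert _mid_amplitude(out.samples[0], fs) == pytest.approx(
            1.0, rel=0.01)

    def test_white_noise_psd_dip_at_60(self):
        fs = 2000.0
        rng = np.random.default_rng(7)
        rec = _recording(rng.standard_normal((1, 200000)), fs=fs)
        out = notch(rec)
        f, pxx = sps.welch(out.samples[0], fs=fs, nperseg=20000)
        at60 = pxx[np.abs(f - 60.0).argmin()]
        neighbors = pxx[(np.abs(f - 55) < 1) | (np.abs(f - 65) < 1)].mean()
        assert 10 * np.log10(neighbors / at60) >= 20

    def test_frequency_beyond_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 1000)), fs=100.0)
        with pytest.raises(ValueError):
            notch(rec, freq=60.0)


class TestEpoching:
    def test_baseline_split_into_36_epochs(self):
        fs = 2000.0
        rec = _recording(np.zeros((2, int(180 * fs))), fs=fs)
        eps = epoch_session(rec, 5.0)
        assert eps.data["baseline"].shape == (36, 2, 10000)

    def test_one_epoch_per_stimulation_event(self, tiny_session):
        recording, _, truth = tiny_session
        eps = epoch_session(recording, 5.0,
                            conditions=truth.config.conditions)
        for cond in truth.config.conditions:
            assert eps.data[cond].shape[0] == truth.config.trials_per_condition
        assert eps.conditions == list(truth.config.conditions)

    def test_zero_length_baseline_rejected(self):
        events = pd.DataFrame({"condition": ["baseline", "6Hz"],
                               "onset_sample": [0, 100],
                               "duration_samples": [50, 500]})
        rec = _recording(np.zeros((2, 1000)), fs=100.0, events=events)
        with pytest.raises(ValueError):
            epoch_session(rec, 5.0)

    def test_event_past_recording_end_rejected(self):
        events = pd.DataFrame({"condition": ["baseline", "6Hz"],
                               "onset_sample": [0, 900],
                               "duration_samples": [600, 400]})
        with pytest.raises(ValueError):
            Recording(subject_id="s", fs=100.0, channel_ids=["a"],
                      samples=np.zeros((1, 1000)), events=events)


class TestSpikeRejection:
    @staticmethod
    def _epochs_with_peaks(peaks):
        data = np.zeros((len(peaks), 1, 100))
        for i, p in enumerate(peaks):
            data[i, 0, 50] = p
        return EpochSet(fs=100.0, channel_ids=["c0"],
                        data={"baseline": data})

    def test_threshold_is_strictly_exceeding(self):
        eps = self._epochs_with_peaks([499.0, 500.0, 501.0, -501.0])
        out, summary = reject_spike_epochs(eps, threshold=500.0)
        assert out.keep["baseline"][:, 0].tolist() == [True, True, False,
                                                       False]
        assert summary["n_rejected"].iloc[0] == 2

    def test_rejection_is_per_channel(self):
        data = np.zeros((2, 2, 100))
        data[0, 1, 10] = 600.0
        eps = EpochSet(fs=100.0, channel_ids=["c0", "c1"],
                       data={"6Hz": data})
        out, _ = reject_spike_epochs(eps)
        assert out.keep["6Hz"][0, 0]          # other channel unaffected
        assert not out.keep["6Hz"][0, 1]

    def test_summary_proportions(self):
        eps = self._epochs_with_peaks([100.0, 700.0, 800.0, 200.0])
        _, summary = reject_spike_epochs(eps)
        assert summary["proportion_rejected"].iloc[0] == pytest.approx(0.5)


class TestDownsample:
    def test_sample_count_scales_by_factor(self):
        data = {"baseline": np.random.default_rng(8)
                .standard_normal((3, 2, 10000))}
        eps = EpochSet(fs=2000.0, channel_ids=["a", "b"], data=data)
        out = downsample(eps, 500.0)
        assert out.data["baseline"].shape == (3, 2, 2500)
        assert out.fs == 500.0

    def test_passband_tone_preserved(self):
        fs = 2000.0
        x = _sine(20.0, fs, 5)
        eps = EpochSet(fs=fs, channel_ids=["a"],
                       data={"baseline": x[None, None, :]})
        out = downsample(eps, 500.0)
        y = out.data["baseline"][0, 0]
        assert np.abs(y[200:-200]).max() == pytest.approx(1.0, rel=0.01)
        f, pxx = sps.periodogram(y, fs=500.0)
        assert f[pxx.argmax()] == pytest.approx(20.0, rel=0.01)

    def test_supra_nyquist_tone_suppressed(self):
        fs = 2000.0
        x = _sine(300.0, fs, 5)
        eps = EpochSet(fs=fs, channel_ids=["a"],
                       data={"baseline": x[None, None, :]})
        out = downsample(eps, 500.0)
        y = out.data["baseline"][0, 0, 200:-200]
        assert 20 * np.log10(1.0 / (np.abs(y).max() + 1e-300)) >= 40

    def test_non_integer_factor_rejected(self):
        eps = EpochSet(fs=2000.0, channel_ids=["a"],
                       data={"baseline": np.zeros((1, 1, 2000))})
        with pytest.raises(ValueError):
            downsample(eps, 600.0)


class TestFullChain:
    def test_stage_order_and_exclusions(self, tiny_config):
        """Line-noise channels are excluded before CAR; labelled exclusions
        never reach the epochs; rejected spikes match the injection."""
        import copy
        cfg = copy.deepcopy(tiny_config)
        cfg.artifacts = sc.ArtifactSpec(
            line_noise={"L-OFC_01": 500.0},
            spikes=[sc.SpikeEvent("L-Amyg_00", 3, 800.0),
                    sc.SpikeEvent("L-Hipp_01", 7, 450.0)])
        recording, table, truth = sc.build_session(cfg)
        table.loc[table.channel_id == "L-OFC_00",
                  "exclude_class"] = "white_matter"
        epochs, table_out, rejection = preprocess_session(
            recording, table, target_rate=500.0,
            conditions=list(cfg.conditions))
        assert "L-OFC_01" not in epochs.channel_ids   # line-noise screened
        assert "L-OFC_00" not in epochs.channel_ids   # label exclusion
        assert bool(table_out.loc[table_out.channel_id == "L-OFC_01",
                                  "noise_flag"].iloc[0])
        # exactly the >500 uV injection is rejected, at its trial slot
        sched = truth.schedule
        cond3 = sched.loc[sched.trial == 3, "condition"].iloc[0]
        # count epochs of that condition before trial 3 to find its index
        prior = ((sched.condition == cond3) & (sched.trial < 3)).sum()
        ch_idx = epochs.channel_ids.index("L-Amyg_00")
        assert not epochs.keep[cond3][prior, ch_idx]
        total_rejected = sum((~m).sum() for m in epochs.keep.values())
        assert total_rejected == 1

    def test_epoch_rate_after_downsampling(self, tiny_session):
        recording, table, _ = tiny_session
        epochs, _, _ = preprocess_session(recording, table,
                                          target_rate=250.0)
        assert epochs.fs == 250.0
        assert epochs.n_samples == int(5.0 * 250.0)
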