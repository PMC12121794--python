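"""Shared fixtures: small synthetic sessions and epoch sets."""

import numpy as np
import pandas as pd
import pytest

import seegcoh as sc

THETA = (4.0, 8.0)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast session: 500 Hz native, short baseline, 4 trials/condition."""
    return sc.SynthConfig(sampling_rate=500.0, baseline_duration=30.0,
                          trials_per_condition=4,
                          regions={"L-Amyg": 2, "L-Hipp": 2, "L-OFC": 2},
                          rng_seed=7)


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    recording, channel_table, truth = sc.build_session(tiny_config)
    return recording, channel_table, truth


@pytest.fixture(scope="session")
def coupled_session():
    """Session with one theta coupling during 20 Hz trials, known oracle.

    The coupling gain is set so the injected in-band power equals the
    background in-band power, giving an expected band MSC of 0.25.
    """
    cfg = sc.SynthConfig(sampling_rate=500.0, baseline_duration=60.0,
                         trials_per_condition=10, noise_exponent=0.0,
                         regions={"A": 1, "B": 1, "C": 2},
                         rng_seed=21)
    sn = sc.inband_noise_power(cfg, THETA)
    cfg.couplings = [sc.CouplingSpec("A", "B", THETA, "20Hz", gain=1.0,
                                     source_power=sn)]
    recording, channel_table, truth = sc.build_session(cfg)
    return cfg, recording, channel_table, truth


@pytest.fixture()
def white_epochs():
    """EpochSet of independent white channels: 6 baseline + 4 stim epochs."""
    rng = np.random.default_rng(3)
    data = {"baseline": rng.standard_normal((6, 4, 2500)),
            "20Hz": rng.standard_normal((4, 4, 2500))}
    return sc.EpochSet(fs=500.0, channel_ids=["c0", "c1", "c2", "c3"],
                       data=data)


def make_region_delta_frame(rows):
    """rows: (region_a, region_b, condition, band, delta[, n])."""
    recs = []
    for r in rows:
        recs.append({"region_a": r[0], "region_b": r[1], "condition": r[2],
                     "band": r[3], "delta": r[4],
                     "n_subjects": r[5] if len(r) > 5 else 1})
    return pd.DataFrame(recs)
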