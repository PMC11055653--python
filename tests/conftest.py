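"""Shared fixtures: small synthetic sessions and clean theta series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import thetalock as tl

CONST_AMP = {k: 40.0 for k in ("default", *tl.EPOCHS)}


def one_trial_table(t_sample: float = 5.0, t_poke: float = 8.0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": 0,
                "modality": "T",
                "object": "A",
                "response_side": "L",
                "correct": True,
                "t_sample_start": t_sample,
                "t_reward_poke": t_poke,
                "withdrawal_latency": 0.5,
            }
        ]
    )


@pytest.fixture(scope="session")
def clean_theta():
    """Noiseless constant-amplitude 8 Hz theta, 60 s, with its truth."""
    params = tl.LfpGenParams(pink_noise_sd=0.0, amp_by_epoch=CONST_AMP)
    gen = tl.gen_lfp(params, one_trial_table(), 60.0, 0)
    series = tl.analytic_phase_amp(tl.bandpass_theta(gen.trace))
    return gen, series


@pytest.fixture(scope="session")
def small_session():
    """Compact 4-trials-per-modality session with two areas and 3 units."""
    units = [
        tl.GroundTruth(
            "hc0", "dHC", mu=0.5, base_rate=8.0,
            kappa={e: {"*": 1.5} for e in tl.EPOCHS}, kappa_outside=1.5,
        ),
        tl.GroundTruth(
            "s1_t", "S1BF", mu=-0.8, base_rate=6.0,
            kappa={"discrimination": {"T": 2.0, "M": 2.0}},
        ),
        tl.GroundTruth("s1_null", "S1BF", mu=0.0, base_rate=5.0, kappa={}),
    ]
    config = tl.SessionGenConfig(
        n_trials_per_modality=4, seed=11, units=units, areas=("dHC", "S1BF"), iti=7.0
    )
    return tl.gen_session(config)


@pytest.fixture(scope="session")
def session_series(small_session):
    """Theta phase series per area of the small session."""
    out = {}
    for area, trace in small_session.lfp.items():
        out[area] = tl.analytic_phase_amp(tl.bandpass_theta(trace))
    return out
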