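"""Shared fixtures: small synthetic calibration sessions, reused across tests.

Everything is generated at run time from fixed seeds; no data files.
"""

import numpy as np
import pytest

import charstream as cs
from charstream.config import draw_calibration_targets
from charstream.synth import default_profile


def make_calibration(
    condition="C",
    n_trials=8,
    n_iterations=8,
    fs=100.0,
    noise_scale=3.0,
    seed=11,
    profile=None,
    **synth_kwargs,
):
    """Generate and preprocess a small calibration session."""
    alphabet = cs.build_alphabet()
    rng = np.random.default_rng(seed)
    targets = draw_calibration_targets(alphabet, n_trials, rng)
    config = cs.ParadigmConfig(
        condition=condition, n_iterations=n_iterations, seed=seed
    )
    schedule = cs.generate_schedule(config, targets, alphabet)
    recording = cs.synthesize(
        schedule,
        profile or default_profile(condition),
        fs=fs,
        noise_scale=noise_scale,
        seed=seed + 1,
        **synth_kwargs,
    )
    recording = cs.bandpass(recording)
    epochs = cs.epoch(recording)
    epochs, _ = cs.minmax_reject(epochs)
    return schedule, recording, epochs


@pytest.fixture(scope="session")
def alphabet():
    return cs.build_alphabet()


@pytest.fixture(scope="session")
def calibration_c():
    """Small condition-C calibration: (schedule, recording, epochs)."""
    return make_calibration()


@pytest.fixture(scope="session")
def cal_epochs(calibration_c):
    return calibration_c[2]
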