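"""Shared fixtures: all data are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ldaep.preprocess import preprocess_recording
from ldaep.simulate import (
    GroundTruth,
    generate_stimulus_sequence,
    simulate_subject_eeg,
)
from ldaep.source import build_head_model


@pytest.fixture(scope="session")
def small_head_model():
    """~100-source fixed-orientation spherical model (shared: building the
    lead field dominates the cost of the source tests)."""
    return build_head_model(n_sources=100)


@pytest.fixture(scope="session")
def noiseless_recording():
    """Zero-noise, zero-blink, zero-artifact subject with the slope pair of
    the canonical recovery example (N1 -0.4, P2 +0.9 µV/dB)."""
    seq = generate_stimulus_sequence(50, seed=101)
    truth = GroundTruth(
        true_slope_n1=-0.4, true_slope_p2=0.9,
        noise_sd_uv=0.0, blink_rate_per_min=0.0, artifact_epoch_fraction=0.0,
    )
    raw = simulate_subject_eeg(seq, truth, seed=102)
    return raw, truth


@pytest.fixture(scope="session")
def noiseless_evoked(noiseless_recording):
    raw, truth = noiseless_recording
    evoked = preprocess_recording(raw, band_hz=None, reject_uv=None)
    return evoked, truth


@pytest.fixture(scope="session")
def noisy_recording():
    """Default study conditions at a reduced event count."""
    seq = generate_stimulus_sequence(300, seed=201)
    truth = GroundTruth()
    raw = simulate_subject_eeg(seq, truth, seed=202)
    return raw, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
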