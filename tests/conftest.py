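"""Shared fixtures: small synthetic sessions and hand-built containers."""

import warnings

import numpy as np
import pytest

from megeeg import (
    ChannelInfo,
    EpochSet,
    Modality,
    Recording,
    SyntheticGroundTruth,
    generate_session,
)

# session sizes used throughout the unit tests: small enough to keep the
# suite fast, large enough for every chain stage to be exercised
MOTOR_KW = dict(n_trials=8, n_eeg=12, n_meg_sites=8, n_motion_bursts=2)
ALPHA_KW = dict(n_cycles=4, cycle_duration=6.0, n_eeg=12, n_meg_sites=8,
                n_motion_bursts=2)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def motor_session():
    """Default-truth motor session (both modalities), reduced sizes."""
    eeg, meg, truth = generate_session(
        "motor", SyntheticGroundTruth(seed=11), **MOTOR_KW
    )
    return eeg, meg, truth


@pytest.fixture(scope="session")
def alpha_session():
    eeg, meg, truth = generate_session(
        "alpha", SyntheticGroundTruth(seed=12), **ALPHA_KW
    )
    return eeg, meg, truth


@pytest.fixture(scope="session")
def quiet_motor_eeg():
    """Artifact-free, effect-free motor EEG recording."""
    eeg, _, truth = generate_session(
        "motor", SyntheticGroundTruth.quiet(seed=13), modalities=("eeg",),
        **MOTOR_KW
    )
    return eeg, truth


def make_recording(n_channels=3, n_samples=500, fs=100.0, seed=0,
                   modality=Modality.EEG, events=None):
    rng = np.random.default_rng(seed)
    channels = [
        ChannelInfo(name=f"CH{i}", modality=modality,
                    position=np.array([0.01 * i, 0.0, 0.09]))
        for i in range(n_channels)
    ]
    return Recording(
        fs=fs,
        data=rng.standard_normal((n_channels, n_samples)),
        channels=channels,
        events=events or [("stim", 100), ("stim", 300)],
    )


def make_epochs(data, fs, window, modality=Modality.EEG, labels=None):
    """EpochSet from a raw trials x channels x samples array."""
    n_ch = data.shape[1]
    channels = [
        ChannelInfo(name=f"CH{i}", modality=modality,
                    position=np.array([0.01 * i, 0.0, 0.09]))
        for i in range(n_ch)
    ]
    return EpochSet(data=data, fs=fs, window=window, channels=channels,
                    labels=labels)


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture
def epochs_factory():
    return make_epochs
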