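"""Shared fixtures: small synthetic sessions reused across test modules.

Session-scoped fixtures keep the suite fast; every fixture is seeded so the
whole run is deterministic.
"""

import numpy as np
import pytest

import cogdepth as cd


@pytest.fixture(scope="session")
def timing200() -> cd.TimingConfig:
    return cd.TimingConfig(sampling_rate_hz=200.0)


@pytest.fixture(scope="session")
def small_sequence() -> cd.StimulusSequence:
    return cd.generate_stimulus_sequence(n_runs=2, n_total=120, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_sequence, timing200) -> cd.Recording:
    """16-channel, 120-trial synthetic session with default effects."""
    return cd.generate_continuous_eeg(
        small_sequence, timing200, cd.EffectSpec(), n_channels=16, seed=7
    )


@pytest.fixture(scope="session")
def clean_epochs(small_recording) -> cd.EpochSet:
    """Fully preprocessed epochs of the small session (100 Hz, −200…2000 ms)."""
    return cd.preprocess(small_recording, target_fs=100.0)


@pytest.fixture(scope="session")
def noise_epochs() -> cd.EpochSet:
    """Label-balanced pure-noise epochs (no class-dependent structure)."""
    rng = np.random.default_rng(42)
    n_trials, n_ch, n_samp = 60, 6, 220
    fs = 100.0
    data = rng.standard_normal((n_trials, n_ch, n_samp)) * 5.0
    labels = np.array((["NT", "DT"] * (n_trials // 2)))
    times = np.arange(-20, 200) * 1000.0 / fs
    return cd.EpochSet(
        data=data,
        labels=labels,
        times=times,
        fs=fs,
        channel_labels=cd.default_channel_labels(6),
    )
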