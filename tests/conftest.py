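import numpy as np
import pandas as pd
import pytest

from empadecode.containers import EpochSet
from empadecode.synth import EffectSpec, make_stimulus_set, make_trial_design, simulate_epochs


def make_sinusoid_epochs(freq_hz: float, fs: float = 500.0, amplitude: float = 1.0,
                         n_trials: int = 4, n_channels: int = 3) -> EpochSet:
    """Pure-sinusoid epochs for filter/resampling amplitude checks."""
    dt = 1000.0 / fs
    n = int(round(700.0 / dt)) + 1
    times = -200.0 + dt * np.arange(n)
    sig = amplitude * np.sin(2 * np.pi * freq_hz * times / 1000.0)
    data = np.tile(sig, (n_trials, n_channels, 1))
    meta = pd.DataFrame(
        {
            "subject_id": 0,
            "group": "low-ALT",
            "task": "CE",
            "stimulus_id": np.arange(n_trials) % 2 + 1,
            "category": ["positive", "negative"] * (n_trials // 2),
        }
    )
    return EpochSet(data, fs, times, [f"ch{i}" for i in range(n_channels)], meta)


def small_epochs(
    category_amplitude: float = 0.0,
    feature_amplitude: float = 0.0,
    n_channels: int = 16,
    repetitions: int = 8,
    n_per_category: int = 10,
    seed: int = 0,
    fs: float = 200.0,
    window: tuple[float, float] = (-200.0, 500.0),
    **effect_kwargs,
):
    """Reduced-scale synthetic subject used across tests."""
    stim = make_stimulus_set(n_per_category=n_per_category, seed=seed)
    design = make_trial_design(stim, repetitions=repetitions, seed=seed)
    eff = EffectSpec(
        category_amplitude=category_amplitude,
        feature_amplitude=feature_amplitude,
        **effect_kwargs,
    )
    epochs = simulate_epochs(
        design, stim, eff, n_channels=n_channels, fs=fs, window=window, seed=seed
    )
    return epochs, stim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid_epochs():
    return make_sinusoid_epochs


@pytest.fixture
def epochs_factory():
    return small_epochs
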