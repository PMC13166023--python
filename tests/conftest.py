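import numpy as np
import pytest

from ssrime.decomposition import CeemdanParams, ceemdan
from ssrime.features import extract_feature_matrix
from ssrime.synthetic import SynthConfig, generate_dataset

FS = 250.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def tone_10hz():
    t = np.arange(0, 3, 1 / FS)
    return np.cos(2 * np.pi * 10 * t)


@pytest.fixture(scope="session")
def two_tone_500hz():
    """Spec'd separation fixture: 25 Hz (amp 1) + 3 Hz (amp 2), 4 s @ 500 Hz."""
    t = np.arange(0, 4, 1 / 500.0)
    return (np.sin(2 * np.pi * 25 * t), 2 * np.sin(2 * np.pi * 3 * t), 500.0)


@pytest.fixture(scope="session")
def fast_ceemdan():
    """Reduced ensemble for desk-scale tests; seeded."""
    return CeemdanParams(n_realizations=20, noise_scale=0.2, seed=7)


@pytest.fixture(scope="session")
def theta_effect_dataset():
    """Two-condition dataset with a frontal θ-gain ratio of 2 and no α effect."""
    cfg = SynthConfig(
        fs=FS, n_epochs_per_condition=30, conditions=("0-back", "2-back"),
        theta_gain=(1.0, 2.0), alpha_gain=(1.0, 1.0), subject_scale_sd=0.2,
        n_subjects=5, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def theta_effect_features(theta_effect_dataset):
    """SS-RIME feature matrix for the θ-effect dataset (shared: expensive)."""
    eeg = theta_effect_dataset
    X = extract_feature_matrix(eeg.data, eeg.fs, "ssrime", n_realizations=20, seed=11)
    return X
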