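import numpy as np
import pytest

from acfkit.containers import CorrelationMatrix, OmicsMatrix
from acfkit.simulate import SimulationConfig, generate_dataset

# the worked 4-sample example used throughout: two classes, hand-checkable
TOY_ENTRIES = np.array([
    [1.0, 0.8, 0.2, 0.4],
    [0.8, 1.0, 0.3, 0.1],
    [0.2, 0.3, 1.0, 0.6],
    [0.4, 0.1, 0.6, 1.0],
])
TOY_IDS = ["s1", "s2", "s3", "s4"]
TOY_LABELS = np.array(["A", "A", "B", "B"], dtype=object)


@pytest.fixture
def toy_corr() -> CorrelationMatrix:
    return CorrelationMatrix(TOY_ENTRIES.copy(), list(TOY_IDS), list(TOY_IDS))


@pytest.fixture
def toy_labels() -> np.ndarray:
    return TOY_LABELS.copy()


def random_missing_matrix(rng, n_samples=6, n_features=20, missing=0.3):
    values = rng.normal(size=(n_samples, n_features))
    drop = rng.random(values.shape) < missing
    # keep every sample observable
    drop[drop.all(axis=1)] = False
    values[drop] = np.nan
    return OmicsMatrix(values)


@pytest.fixture
def zero_noise_dataset():
    """Perfectly separable draw: samples duplicate their class centers."""
    cfg = SimulationConfig(n_features=1000, sigma_feature=0.0,
                           class_sizes=(20, 20, 20), missing_fraction=0.0,
                           covariate=None, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def noisy_dataset():
    """Small noisy draw with missing values for equivalence checks."""
    cfg = SimulationConfig(n_features=800, sigma_feature=2.0,
                           class_sizes=(15, 12, 18), missing_fraction=0.25,
                           covariate=None, seed=21)
    return generate_dataset(cfg)
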