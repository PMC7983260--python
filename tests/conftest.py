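import numpy as np
import pytest

from vemgae import AssociationMatrix, FeatureMatrix, TrainConfig, generate
from vemgae.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured (Y, X_l, X_d, truth) instance for fast tests."""
    spec = SyntheticSpec(
        m=18, n=22, latent_rank=3, n_positives=50,
        feature_dim_l=10, feature_dim_d=14,
        feature_noise_sd=0.3, bernoulli_base_rate=0.1, seed=5,
    )
    return generate(spec)


@pytest.fixture
def tiny_config():
    return TrainConfig(epochs=6, hidden_dim=16, knn_k=3, seed=3)


@pytest.fixture
def toy_assoc():
    values = np.zeros((3, 2))
    values[1, 0] = 1.0
    return AssociationMatrix(values, ["r1", "r2", "r3"], ["c1", "c2"])


@pytest.fixture
def gaussian_features():
    rng = np.random.default_rng(11)
    return FeatureMatrix(rng.random((6, 4)), [f"n{i}" for i in range(6)], "gaussian")
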