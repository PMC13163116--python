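import warnings

import numpy as np
import pytest

from histode import (
    DEConfig,
    ExtractionConfig,
    FitnessFunction,
    SyntheticSpec,
    generate_features,
    generate_images,
    train_head,
)

warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def planted8():
    """d=8 planted fixture: 2 informative columns, 2 classes."""
    spec = SyntheticSpec(
        d=8, informative_idx=frozenset({1, 4}), n_per_class=50,
        n_classes=2, effect_size=3.0, seed=3,
    )
    data, truth = generate_features(spec)
    return data, truth


@pytest.fixture(scope="session")
def planted32():
    """d=32 planted fixture: 4 informative columns, 5 classes, effect 3."""
    spec = SyntheticSpec(
        d=32, informative_idx=frozenset({0, 5, 9, 20}), n_per_class=100,
        n_classes=5, effect_size=3.0, seed=7,
    )
    data, truth = generate_features(spec)
    return data, truth


@pytest.fixture(scope="session")
def shared_fitness_8(planted8):
    """One cached fitness function over the d=8 fixture, shared across
    DE runs and the exhaustive oracle."""
    data, _ = planted8
    return FitnessFunction(data, DEConfig(seed=0))


@pytest.fixture(scope="session")
def image_tree(tmp_path_factory):
    """Small procedural-texture image tree: 3 classes × 5 images, 64 px."""
    root = tmp_path_factory.mktemp("images")
    generate_images(n_per_class=5, n_classes=3, side=64, seed=1, out_dir=root)
    return root


@pytest.fixture(scope="session")
def small_config():
    """Reduced head geometry for fast extraction tests."""
    return ExtractionConfig(
        input_side=64, backbone_out_channels=64, hidden_dim=96,
        feature_dim=48, epochs=5, batch_size=8, seed=0,
    )


@pytest.fixture(scope="session")
def trained_extractor(image_tree, small_config):
    return train_head(image_tree, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
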