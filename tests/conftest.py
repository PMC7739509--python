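import numpy as np
import pytest

from sheartex import (
    FUSION_1,
    build_shearlet_system,
    extract_fused_features,
    generate_dataset,
    shearlet_transform,
)

DATASET_SEED = 7
FOLD_SEED = 17


@pytest.fixture(scope="session")
def system64():
    return build_shearlet_system(64, 64, scales=4, directions_per_scale=8)


@pytest.fixture(scope="session")
def random_image64():
    return np.random.default_rng(0).random((64, 64))


@pytest.fixture(scope="session")
def coeff_stack64(system64, random_image64):
    return shearlet_transform(random_image64, system64)


@pytest.fixture(scope="session")
def texture_dataset():
    """The study-scale synthetic dataset: 4 classes x 50 images, 128 px,
    noise sd 0.3."""
    return generate_dataset(
        n_classes=4, n_per_class=50, size=128, seed=DATASET_SEED, noise_sd=0.3
    )


@pytest.fixture(scope="session")
def fusion1_matrix(texture_dataset):
    """Fusion #1 feature matrix of the full synthetic dataset (expensive;
    shared by the end-to-end and reduction tests)."""
    return extract_fused_features(
        texture_dataset.images, FUSION_1, labels=texture_dataset.labels
    )
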