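import logging

import numpy as np
import pytest

from neurotact.experiments import encode_dataset
from neurotact.features_classify import FeatureMatrix, build_feature_matrix
from neurotact.innervation import build_innervation
from neurotact.synth_rig import default_texture_library

logging.getLogger("neurotact").setLevel(logging.ERROR)

SPEEDS = [40.0, 50.0, 60.0, 70.0, 80.0, 90.0]

_feature_cache: dict[int, FeatureMatrix] = {}


def full_feature_matrix(seed: int) -> FeatureMatrix:
    """Features of the full 10-texture x 6-speed x 10-rep dataset (600 trials).

    Cached per seed: several protocol checks share the same dataset.
    """
    if seed not in _feature_cache:
        trials = encode_dataset(default_texture_library(), SPEEDS, 10, seed)
        _feature_cache[seed] = build_feature_matrix(trials)
    return _feature_cache[seed]


@pytest.fixture(scope="session")
def imap0():
    return build_innervation(seed=0)


@pytest.fixture(scope="session")
def small_trials():
    """4 textures x 2 speeds x 2 reps, encoded; cheap shared fixture."""
    specs = default_texture_library()[:4]
    return encode_dataset(specs, [40.0, 90.0], 2, seed=1)


@pytest.fixture(scope="session")
def features600():
    return full_feature_matrix(0)


def random_feature_matrix(n_per_class: int, n_classes: int, n_features: int,
                          separation: float, seed: int) -> FeatureMatrix:
    """Synthetic Gaussian-cluster feature matrix for classifier tests."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k in range(n_classes):
        X.append(np.abs(rng.normal(10.0 + separation * k, 1.0,
                                   size=(n_per_class, n_features))))
        y.extend([k] * n_per_class)
    X = np.vstack(X)
    names = [f"sa1_{i + 1}" for i in range(n_features)]
    groups = ["SA-I"] * n_features
    y = np.array(y)
    speeds = np.full(len(y), 60.0)
    from neurotact.features_classify import speed_class_labels

    return FeatureMatrix(X, names, groups, y, speed_class_labels(speeds))
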