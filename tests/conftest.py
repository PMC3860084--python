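import numpy as np
import pytest

import gaitclass as gc


@pytest.fixture(scope="session")
def small_session():
    """Noise-free synthetic session with 24 epochs and its ground truth."""
    spec = gc.SessionSpec(
        class_mix={"walking": 10, "stair_climbing": 7, "stair_descending": 7},
        noise_sd=0.0)
    return gc.generate_session(spec, seed=11)


@pytest.fixture(scope="session")
def feature_clusters():
    """Well-separated 16-D Gaussian clusters (650 points, 3 classes)."""
    counts = {"walking": 300, "stair_climbing": 180, "stair_descending": 170}
    return gc.generate_feature_clusters(counts, seed=7)


@pytest.fixture(scope="session")
def mapped_clusters(feature_clusters):
    """Sammon embedding + trained surrogate for the cluster fixture."""
    X, labels = feature_clusters
    emb = gc.sammon_map(X, seed=7)
    surr = gc.train_surrogate(X, emb.Y, seed=7)
    return X, labels, emb, surr
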