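import numpy as np
import pytest

from rarelulc.modis_preprocess import preprocess_scene
from rarelulc.synthetic_scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def tiny_scene():
    """Small scene shared across test modules (120 pixels, fixed seed)."""
    return generate_scene(SceneConfig(rows=12, cols=10), seed=1)


@pytest.fixture(scope="session")
def tiny_features(tiny_scene):
    features, report = preprocess_scene(tiny_scene)
    X = features.drop(columns=["pixel_id", "label"]).to_numpy()
    y = features["label"].to_numpy()
    return X, y, features


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_blobs(rng, counts, centers=None, sd=0.3, dim=4):
    """Well-separated Gaussian class blobs for resampling/experiment tests."""
    if centers is None:
        centers = 10.0 * np.arange(len(counts))[:, None] * np.ones(dim)
    X, y = [], []
    for cid, n in enumerate(counts):
        X.append(rng.normal(centers[cid], sd, size=(n, dim)))
        y.append(np.full(n, cid))
    return np.vstack(X), np.concatenate(y)
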