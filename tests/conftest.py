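import numpy as np
import pytest

from obiaveg import RasterScene, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene() -> RasterScene:
    """A small labeled two-class scene shared by read-only tests."""
    return generate_scene(SceneConfig(height=48, width=48, n_segments=24, seed=101))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240506)


def make_random_table(rng, n_rows=None, n_feat=None, n_classes=None):
    """Small random labeled table: continuous features, arbitrary classes."""
    n_rows = n_rows or int(rng.integers(8, 51))
    n_feat = n_feat or int(rng.integers(1, 7))
    n_classes = n_classes or int(rng.integers(2, 4))
    X = rng.standard_normal((n_rows, n_feat))
    y = rng.integers(0, n_classes, size=n_rows)
    # guarantee at least two classes are present
    if np.unique(y).size < 2:
        y[0] = (y[1] + 1) % n_classes
    labels = np.asarray([f"c{v}" for v in y])
    names = [f"f{j}" for j in range(n_feat)]
    return X, y, labels, names
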