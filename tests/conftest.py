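import numpy as np
import pytest

from plexseg import ClassProfile, SceneSpec, generate_scene
from plexseg.model import SegmentationModel, tiny_model_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene with 10 single-class cells."""
    return generate_scene(SceneSpec(height=128, width=128, n_cells=10,
                                    transcript_rate=20.0, seed=7))


@pytest.fixture(scope="session")
def two_class_scene():
    spec = SceneSpec(height=128, width=128, n_cells=12,
                     class_profiles=[ClassProfile("tumor", 9.0),
                                     ClassProfile("immune", 7.0)],
                     seed=11)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def tiny_model(small_scene):
    """Untrained tiny model matching the session scene's channel count."""
    return SegmentationModel(tiny_model_config(
        in_channels=small_scene.image.shape[0], n_classes=1, n_queries=50, seed=3))


def random_blob(rng, h=32, w=32, n_seeds=3):
    """Random connected-ish blob mask with at least one foreground pixel."""
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_seeds):
        r, c = rng.integers(2, h - 2), rng.integers(2, w - 2)
        rr = rng.integers(1, 5)
        yy, xx = np.mgrid[0:h, 0:w]
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= rr ** 2
    return mask
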