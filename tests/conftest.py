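import numpy as np
import pytest

from emoelm import CVSetting, ObjectiveEvaluator, SyntheticSceneSpec, flatten_scene, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_samples(rng):
    """Small well-conditioned sample matrix in [0, 1]."""
    return rng.random((30, 5))


@pytest.fixture
def tiny_evaluator(tiny_samples):
    return ObjectiveEvaluator(tiny_samples, L=3, cv=CVSetting(3, seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """3-class 30x30 scene with 20 bands, moderate noise."""
    return generate_scene(
        SyntheticSceneSpec(n_classes=3, n_bands=20, height=30, width=30, noise_std=0.05, seed=7)
    )


@pytest.fixture(scope="session")
def small_scene_samples(small_scene):
    return flatten_scene(small_scene)
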