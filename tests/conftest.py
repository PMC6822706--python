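import numpy as np
import pytest

from mycovision import presets, synthetic


@pytest.fixture(scope="session")
def spore_scene():
    """Brightfield spore scene: 25 spores + 10 distractors, low noise."""
    return synthetic.generate_spore_scene(
        n_spores=25, n_distractors=10, noise_sigma=0.05, seed=11, shape=(512, 512)
    )


@pytest.fixture(scope="session")
def mycelium_scene():
    """Planted-tree mycelium scene with gradient and noise (512 px)."""
    return synthetic.generate_mycelium_scene(
        n_branches=8,
        branch_length_range=(50.0, 120.0),
        gradient_amplitude=0.1,
        noise_sigma=0.05,
        seed=21,
        shape=(512, 512),
    )


@pytest.fixture(scope="session")
def trap_scene():
    return synthetic.generate_trap_scene(
        n_traps=6, background_hyphae=8, seed=31, shape=(640, 640)
    )


@pytest.fixture
def spore_params():
    return presets.spore_scene_params()


@pytest.fixture
def mycelium_params():
    return presets.mycelium_scene_params()


@pytest.fixture
def trap_params():
    return presets.trap_scene_params()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
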