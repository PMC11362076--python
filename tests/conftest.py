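import numpy as np
import pytest

from deshade import SceneConfig, generate_scene, vegetation_mask
from deshade.study import recovery_study


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene (32-px plots, 36 samples) shared by fast tests."""
    cfg = SceneConfig(seed=42, plot_size=32, samples_per_plot=2)
    cube, truth = generate_scene(cfg)
    return cfg, cube, truth


@pytest.fixture(scope="session")
def default_scene():
    """One full-size scene under the default study conditions."""
    cfg = SceneConfig(seed=101)
    cube, truth = generate_scene(cfg)
    return cfg, cube, truth


@pytest.fixture(scope="session")
def default_scene_mask(default_scene):
    cfg, cube, truth = default_scene
    return vegetation_mask(cube, seed=cfg.seed)


@pytest.fixture(scope="session")
def study_frame():
    """The 20-scene de-interference study (shared by the heavy checks)."""
    return recovery_study(n_scenes=20, base_seed=201)


def make_cube(rng, nrows=6, ncols=6, nbands=40, lo=400.0, step=2.2):
    """Small random cube helper for unit tests."""
    from deshade import SpectralCube

    wl = lo + step * np.arange(nbands)
    data = rng.uniform(0.05, 0.6, size=(nrows, ncols, nbands))
    return SpectralCube(data, wl)
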