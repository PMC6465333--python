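import numpy as np
import pytest

from cotranscoloc.synthetic import SceneParams, simulate_scene


@pytest.fixture
def small_scene_params() -> SceneParams:
    """A compact two-colour scene used across modules."""
    return SceneParams(
        shape=(10, 180, 220),
        n_cells=3,
        cell_radii_px=(20.0, 25.0),
        nucleus_radii_px=(8.0, 10.0),
        spots_per_cell_ch1=40,
        spots_per_cell_ch2=40,
        coloc_fraction=0.5,
        coloc_jitter_nm=15.0,
        seed=42,
    )


@pytest.fixture
def small_scene(small_scene_params):
    return simulate_scene(small_scene_params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
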