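import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cle_afq import SceneSpec, render_scene
from cle_afq.simulate import NoiseParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spots_frame():
    """30 planted 2 µm spots at default contrast, with ground truth."""
    spec = SceneSpec(n_spots=30, spot_diameter_um=(2.0, 2.0), seed=11)
    return render_scene(spec, "BP", seed=11)


@pytest.fixture(scope="session")
def blank_frame():
    """Object-free frame: background plus noise only."""
    spec = SceneSpec(seed=101)
    return render_scene(spec, "BP", seed=101)[0]


@pytest.fixture(scope="session")
def mixed_frame():
    """One frame carrying all object classes plus diffuse AF."""
    spec = SceneSpec(
        n_spots=30, n_small_cells=4, n_large_cells=2, n_fibers=2, n_round=3,
        diffuse_level=95.0, seed=54,
    )
    return render_scene(spec, "BP", seed=54)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Noise-free render of each object class for geometry checks."""
    spec = SceneSpec(
        n_spots=5, n_small_cells=3, n_large_cells=2, n_round=2,
        noise=NoiseParams(0.0, 0.0), seed=77,
    )
    return render_scene(spec, "BP", seed=77)
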