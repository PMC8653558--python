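import numpy as np
import pytest

from discdegen import load_presets
from discdegen.study_design import default_design
from discdegen.synthetic import PhantomGeometry


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def flat_geometry():
    """Noise-free geometry with a 4 mm gap for closed-form height checks."""
    return PhantomGeometry(
        a_mm=7.5, b_mm=5.0, base_gap_mm=4.0, points_per_endplate=800,
        surface_roughness_sd_mm=0.0, np_fraction=0.5, blend_mm=0.5,
    )


def grid_cloud(z, n=10, extent=10.0):
    """Regular n x n grid at constant height z, as an (n*n, 3) array."""
    xs = np.linspace(0.0, extent, n)
    xx, yy = np.meshgrid(xs, xs)
    return np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, float(z))])
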