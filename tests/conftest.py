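import numpy as np
import pytest

from beadstress.calibration import PAA_5_0225
from beadstress.imaging import SpheroidGeometry
from beadstress.pipeline import run_full_pipeline
from beadstress.synthetic import SceneConfig, make_cell_field, make_spheroid_scene


@pytest.fixture(scope="session")
def paa():
    """Linear 15 kPa bead constitutive law."""
    return PAA_5_0225


@pytest.fixture(scope="session")
def scene_small(paa):
    """10-spheroid cohort under the default study conditions (seeded)."""
    cfg = SceneConfig(n_spheroids=10, seed=11)
    return make_spheroid_scene(cfg, paa)


@pytest.fixture(scope="session")
def result_small(scene_small, paa):
    return run_full_pipeline(scene_small, paa, seed=11)


@pytest.fixture(scope="session")
def cell_field():
    """One seeded step cell field (180 cells, transition at R0/3)."""
    labels, truth = make_cell_field(120.0, 180, seed=7)
    npx = labels.shape[0]
    geom = SpheroidGeometry(
        center=(npx / 2.0, npx / 2.0, 0.0),
        radius=120.0,
        contour_area=float(np.pi * 120.0**2),
    )
    return labels, truth, geom
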