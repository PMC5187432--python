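import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from leafmorph.morphometry import ShapeParameters, WingOutline
from leafmorph.synthetic import (
    SyntheticPopulationConfig,
    draw_shape_parameters,
    synthesize_outline,
)


@pytest.fixture(scope="session")
def default_table():
    """One synthetic study population at the default study conditions."""
    return draw_shape_parameters(SyntheticPopulationConfig(rng_seed=123))


@pytest.fixture(scope="session")
def tegmen_outline():
    """Outline at the mimicking-component mean shape, 40 mm long."""
    params = ShapeParameters(ratio_wl=0.36, ratio_field_width=1.0,
                             ratio_field_area=1.0,
                             circularity_anterior=0.33)
    return synthesize_outline(params, 40.0, taxon_id="mean_mimic")


@pytest.fixture()
def circle_outline():
    """Unit circle with a horizontal diameter as the split polyline."""
    theta = np.linspace(0.0, 2.0 * np.pi, 721)[:-1]
    vertices = np.column_stack([np.cos(theta), np.sin(theta)])
    split = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
    return WingOutline(vertices=vertices, split_polyline=split,
                       taxon_id="disk")


def ellipse_outline(a=2.0, b=1.0, n=512, with_split=True):
    theta = np.linspace(0.0, 2.0 * np.pi, n + 1)[:-1]
    vertices = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    split = (np.array([[-a, 0.0], [0.0, 0.0], [a, 0.0]])
             if with_split else None)
    return WingOutline(vertices=vertices, split_polyline=split,
                       taxon_id="ellipse")
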