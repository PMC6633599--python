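import numpy as np
import pandas as pd
import pytest

from tissuekin.midline import Midline
from tissuekin.specs import FlowSpec, SceneSpec, SurfaceSpec
from tissuekin.synthetic import generate_tracks


@pytest.fixture
def midline_y():
    """Midline along the y-axis through the origin (VP at -y, AP at +y)."""
    return Midline((0.0, -150.0, 0.0), (0.0, 150.0, 0.0))


@pytest.fixture
def small_translation_scene():
    return SceneSpec(
        flow=FlowSpec("translation", velocity=(0.05, 0.02, 0.0)),
        surface=SurfaceSpec("flat"),
        n_cells=40, n_frames=5, frame_interval=60.0, noise_sd=0.0, seed=7,
    )


@pytest.fixture
def small_translation_tracks(small_translation_scene):
    return generate_tracks(small_translation_scene)


def fan_area(vertices) -> float:
    """Independent polygon-area oracle: triangle-fan decomposition from the
    first vertex, summing signed triangle areas."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b, c = v[0], v[i], v[i + 1]
        total += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    return abs(total)
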