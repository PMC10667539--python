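import numpy as np
import pytest

from keratovae import pipeline, synthmap


@pytest.fixture(scope="session")
def scale():
    return synthmap.default_color_scale()


@pytest.fixture(scope="session")
def rendered_fixture(scale):
    """One keratoconic map rendered with annotation clutter."""
    params = synthmap.MapParams(
        pattern="inferior_cone", ave_k=48.0, cyl=3.0, axis=0.4,
        cone_amplitude=6.0, cone_center=(0.05, 0.4), cone_width=0.2,
        label="kcn")
    canvas = synthmap.CanvasConfig(annotation_seed=3)
    side = int(round(2 * canvas.radius_frac * canvas.size[0]))
    field, mask = synthmap.curvature_field(params, (side, side))
    rendered = synthmap.render_map(field, mask, scale, canvas)
    return params, field, mask, rendered


@pytest.fixture(scope="session")
def small_processed_cohort():
    """A 12+12 fully preprocessed cohort shared across model tests."""
    return pipeline.generate_processed_cohort(12, 12, seed=9, canvas_size=160)
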