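import numpy as np
import pytest

import wormtrace as wt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def straight_ridge():
    """Noiseless horizontal ridge from x=15 to x=185 at y=40, 1.95 nm pixels."""
    line = np.array([[15.0, 40.0], [185.0, 40.0]])
    image = wt.render_image(line, wt.RenderParams(), pixel_size=1.95)
    return image, line


@pytest.fixture(scope="session")
def arc_ridge():
    """Noiseless half-circle ridge of radius 50 nm."""
    radius, center = 50.0, np.array([80.0, 80.0])
    t = np.linspace(-np.pi / 2, np.pi / 2, 400)
    arc = center + radius * np.column_stack([np.cos(t), np.sin(t)])
    image = wt.render_image(arc, wt.RenderParams(), pixel_size=1.95)
    return image, arc, radius, center
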