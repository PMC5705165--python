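import numpy as np
import pytest

from actomotion import BoundaryCurve, build_mesh, unit_circle


@pytest.fixture(scope="session")
def circle_curve():
    return unit_circle(256)


@pytest.fixture(scope="session")
def circle_mesh(circle_curve):
    return build_mesh(circle_curve, 0.16)


@pytest.fixture(scope="session")
def circle_mesh_fine(circle_curve):
    return build_mesh(circle_curve, 0.08)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_ellipse(a=2.0, b=1.0, n=1024):
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    # approximate perimeter for the target spacing
    per = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    return BoundaryCurve(pts, target_spacing=per / n)


@pytest.fixture(scope="session")
def ellipse_curve():
    return make_ellipse()
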