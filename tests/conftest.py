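import numpy as np
import pytest

from trimorph import synth_valve as sv


@pytest.fixture
def circle_annulus():
    return sv.build_annulus("circle", radius=20.0)


@pytest.fixture
def ellipse_annulus():
    return sv.build_annulus("ellipse", semi_axis_a=25.1, semi_axis_b=21.55)


@pytest.fixture
def saddle_annulus():
    return sv.build_annulus("saddle", radius=20.0, saddle_height=5.0)


@pytest.fixture
def paraboloid_spec(circle_annulus):
    # tenting depth chosen so the closed-form tenting volume h*pi*r^2/2 is 6 mL
    return sv.LeafletPhantomSpec(
        annulus=circle_annulus, tenting_profile="paraboloid", tenting_depth=9.549
    )


@pytest.fixture
def flat_spec(circle_annulus):
    return sv.LeafletPhantomSpec(
        annulus=circle_annulus, tenting_profile="flat", tenting_depth=0.0
    )


def rigid_transform(rng):
    """Random rotation + translation as a (R, t) pair."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-30, 30, size=3)
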