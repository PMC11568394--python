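import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cobbkit as ck

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def rectangle_vertebra(
    label, center, orientation_deg, width=60.0, height=40.0
) -> ck.VertebraKeypoints:
    """Rigid rectangle whose endplates are tilted by ``orientation_deg``.

    Orientation follows the synthetic-spine convention: the tangent angle
    arctan(dx/dy) of the centerline, so the endplate direction is
    (cos a, -sin a) for a = orientation in radians.
    """
    a = np.radians(orientation_deg)
    u = np.array([np.cos(a), -np.sin(a)])  # endplate direction
    t = np.array([np.sin(a), np.cos(a)])  # craniocaudal direction
    c = np.asarray(center, float)
    w2, h2 = width / 2.0, height / 2.0
    corners = np.array(
        [c - w2 * u - h2 * t, c + w2 * u - h2 * t, c + w2 * u + h2 * t, c - w2 * u + h2 * t]
    )
    return ck.VertebraKeypoints(label=label, corners=corners)


def stacked_annotation(
    orientations, subject_id="stack", spacing=50.0, x0=200.0, y0=100.0, noise=0.0, rng=None
) -> ck.SpineAnnotation:
    """Vertical stack of rectangle vertebrae with the given endplate tilts."""
    verts = []
    for i, o in enumerate(orientations):
        v = rectangle_vertebra(i, (x0, y0 + i * spacing), o)
        if noise > 0:
            v = ck.VertebraKeypoints(
                label=i, corners=v.corners + rng.normal(0, noise, size=(4, 2))
            )
        verts.append(v)
    return ck.SpineAnnotation(subject_id=subject_id, vertebrae=verts)


@pytest.fixture
def straight_annotation() -> ck.SpineAnnotation:
    return stacked_annotation([0.0] * 8)


@pytest.fixture
def c_curve() -> tuple[ck.SpineAnnotation, ck.GroundTruth]:
    return ck.generate_spine(ck.single_curve_params(30.0))


def random_annotation(seed: int) -> ck.SpineAnnotation:
    """A random valid annotation for round-trip / property tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 20))
    spacing = float(rng.uniform(45, 60))
    orientations = rng.uniform(-30, 30, size=n)
    ann = stacked_annotation(
        orientations,
        subject_id=f"rand-{seed}",
        spacing=spacing,
        x0=float(rng.uniform(100, 400)),
        y0=float(rng.uniform(50, 150)),
        noise=1.0,
        rng=rng,
    )
    return ann
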