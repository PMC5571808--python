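"""Shared fixtures: small synthetic detector images with known structure."""

import numpy as np
import pytest

from scatterheal import (
    Background,
    DetectorImage,
    IsotropicRing,
    MaskSpec,
    Beamstop,
    GapBand,
    PeakSet,
    SceneSpec,
    render_mask,
    render_scene,
)
from scatterheal.geometry import _pixel_coords, remesh_to_polar

SMALL_SHAPE = (256, 256)
SMALL_CENTER = (124.3, 130.1)  # generic fractional center, off the lattice symmetry point


@pytest.fixture(scope="session")
def ring_image():
    """Noise-free isotropic Gaussian ring on a constant background, full mask."""
    r, _ = _pixel_coords(SMALL_SHAPE, SMALL_CENTER)
    intensity = 10.0 + 100.0 * np.exp(-((r - 60.0) ** 2) / (2.0 * 6.0**2))
    return DetectorImage(intensity, np.ones(SMALL_SHAPE, bool), SMALL_CENTER)


@pytest.fixture(scope="session")
def ring_polar(ring_image):
    return remesh_to_polar(ring_image)


@pytest.fixture(scope="session")
def masked_iso_scene():
    """Isotropic scene with a realistic mask (beamstop + arm + module gap)."""
    scene = SceneSpec(
        shape=SMALL_SHAPE,
        center=SMALL_CENTER,
        features=[IsotropicRing(q0=60.0, width=8.0, amplitude=120.0)],
        background=Background(constant=50.0),
        noise=None,
        seed=0,
    )
    mask = render_mask(
        MaskSpec(
            elements=[Beamstop(radius=10.0, arm_width=5.0, arm_angle=270.0), GapBand(0, 90, 7)],
            center=scene.center,
        ),
        scene.shape,
    )
    render = render_scene(scene)
    return DetectorImage(render.image, mask, scene.center), render.truth


@pytest.fixture(scope="session")
def sixfold_scene():
    """Noise-free sixfold peak ring on a constant background (512 px frame)."""
    scene = SceneSpec(
        shape=(512, 512),
        center=(250.3, 261.7),
        features=[
            PeakSet(q0=120.0, width_r=6.0, width_chi=8.0, fold=6, amplitude=200.0, phase=13.0)
        ],
        background=Background(constant=40.0),
        noise=None,
        seed=0,
    )
    return scene, render_scene(scene)
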