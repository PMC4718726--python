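import numpy as np
import pytest

from patchtension import imaging
from patchtension.synthetic import (ChannelParams, MembraneModel,
                                    PipetteGeometry, render_patch_image)


@pytest.fixture(scope="session")
def geometry():
    return PipetteGeometry()


@pytest.fixture(scope="session")
def membrane():
    return MembraneModel()


@pytest.fixture(scope="session")
def channel():
    return ChannelParams()


@pytest.fixture(scope="session")
def rendered_phantom(geometry):
    """Noise-free phantom at the representative 2.87 um radius."""
    return render_patch_image(geometry, 2.87, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def phantom_image(rendered_phantom):
    """The phantom without its ground-truth wall lines attached."""
    img = rendered_phantom.image
    return imaging.PatchImage(intensities=img.intensities,
                              pixel_size=img.pixel_size)


def circle_points(radius, center=(0.0, 0.0), n=20, arc=2 * np.pi,
                  jitter=0.0, seed=0, phase=0.0):
    """Points on (or near) a circular arc, for fit oracles."""
    rng = np.random.default_rng(seed)
    ang = phase + np.linspace(0.0, arc, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(ang),
                           center[1] + radius * np.sin(ang)])
    if jitter:
        pts = pts + rng.normal(0.0, jitter, pts.shape)
    return pts
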