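import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from coroseg.patches import Patch
from coroseg.volume import CTVolume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def constant_volume():
    """A 12 x 12 x 12 mm volume of 400 HU at the working resolution."""
    return CTVolume(np.full((48, 48, 48), 400.0), np.full(3, 0.25))


def make_patch(values, view_tag="perpendicular", origin=(0.0, 0.0, 0.0)):
    """Wrap a 32x32 array as a patch on the xy-plane."""
    basis = np.array([[1.0, 0, 0], [0, 1.0, 0]])
    return Patch(np.asarray(values, dtype=float), np.asarray(origin, float),
                 basis, view_tag)


def disc_patch(fg=400.0, bg=30.0, radius_px=4.0, center=(16, 16),
               noise=None, rng=None):
    """A synthetic cross-section: a bright disc on a dark background."""
    ii, jj = np.indices((32, 32))
    values = np.full((32, 32), bg)
    disc = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius_px ** 2
    values[disc] = fg
    if noise:
        values = values + rng.normal(0, noise, values.shape)
    return make_patch(values), disc


@pytest.fixture
def tube_volume():
    """A binary tube of radius 1 mm along z, axis through a voxel centre."""
    shape = (48, 48, 48)
    spacing = 0.25
    ax = np.arange(shape[0]) * spacing
    axis_xy = (6.0, 6.0)
    dx = ax[:, None] - axis_xy[0]
    dy = ax[None, :] - axis_xy[1]
    inside = (dx ** 2 + dy ** 2 <= 1.0 ** 2)
    vox = np.where(inside[:, :, None], 400.0, 30.0) * np.ones((1, 1, shape[2]))
    return CTVolume(vox, np.full(3, spacing)), np.array([*axis_xy, 6.0])
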