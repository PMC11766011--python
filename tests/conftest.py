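import numpy as np
import pytest

from vsdgate import steered_deactivation as sd
from vsdgate import structures_io as sio


@pytest.fixture
def toy_wt():
    return sio.toy_vsd("WT")


@pytest.fixture
def toy_r1e():
    return sio.toy_vsd("R1E")


@pytest.fixture
def quick_mc():
    """Cheap MC settings for unit tests (determinism/contract checks only)."""
    return sd.MCConfig(seed=0, termination_window=8, max_moves=20,
                       descent_iters=6, rigid_helix="S4")


def two_charge_structure(distance: float = 9.0):
    """Two free charged sites (Arg CZ / Glu CD) on different chains."""
    atoms = [
        sio.Atom("CZ", "ARG", 1, "A", np.array([0.0, 0.0, 0.0])),
        sio.Atom("CD", "GLU", 1, "B", np.array([distance, 0.0, 0.0])),
    ]
    return sio.Structure(atoms, {})


def rotate_about_z(structure, indices, angle_deg, center=None):
    """Rotate selected atoms about a vertical axis (helper for rotation tests)."""
    coords = structure.coords
    if center is None:
        center = coords[indices, :2].mean(axis=0)
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    xy = coords[indices, :2] - center
    coords[indices, 0] = c * xy[:, 0] - s * xy[:, 1] + center[0]
    coords[indices, 1] = s * xy[:, 0] + c * xy[:, 1] + center[1]
    structure.set_coords(coords)
    return structure
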