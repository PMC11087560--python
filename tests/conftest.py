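"""Shared fixtures: phantoms are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from auriclometry.synthetic import EarSpec, make_head_with_ears


# scaled-down ear for voxel-scale tests: the 13 mm protrusion keeps a 4 mm
# air gap behind the flap (width·sin(AC) = 9 mm), which must exceed the CT
# voxel size or the gap fuses shut in voxel space
SMALL_EAR = dict(
    length_mm=30.0,
    width_mm=18.0,
    inclination_deg=20.0,
    protrusion_mm=13.0,
    ac_angle_deg=30.0,
)


@pytest.fixture(scope="session")
def default_head():
    """Full-size head phantom with the default ear parameters and a small
    bilateral offset; session-scoped because construction is deterministic."""
    mesh, truth = make_head_with_ears(
        EarSpec(center_offset=(2.0, 3.0)), EarSpec()
    )
    return mesh, truth


@pytest.fixture(scope="session")
def small_head():
    """Scaled-down head phantom suited for voxel-scale (CT) tests."""
    mesh, truth = make_head_with_ears(
        EarSpec(**SMALL_EAR, center_offset=(1.0, 1.5)),
        EarSpec(**SMALL_EAR),
        head_axes=(40.0, 50.0, 45.0),
        n_rings=96,
        n_phi=192,
        flap_thickness_mm=2.0,
    )
    return mesh, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240510)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    return Q * np.sign(np.linalg.det(Q))


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=[2.0, 2.0, 2.0])
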