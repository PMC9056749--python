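"""Shared fixtures: small systems with geometry chosen by hand."""

import numpy as np
import pytest

from hydrolayer.trajectory_io import Box, Topology, Trajectory, water_topology
from hydrolayer.synthetic_data import _rigid_water_h


@pytest.fixture
def box10() -> Box:
    return Box.cubic(10.0)


@pytest.fixture
def water_dimer():
    """Donor–acceptor pair: H···O = 2.4 Å, O···O = 3.3 Å (bonded geometry).

    Donor O at origin with one H pointing along +x at 0.9 Å; acceptor O at
    x = 3.3.  Remaining hydrogens point away from the partner.
    """
    coords = np.array([
        [0.0, 0.0, 0.0],   # donor O
        [0.9, 0.0, 0.0],   # donor H on the O–O axis
        [-0.3, 0.9, 0.0],  # donor H away
        [3.3, 0.0, 0.0],   # acceptor O
        [3.9, 0.7, 0.0],   # acceptor H away
        [3.9, -0.7, 0.0],  # acceptor H away
    ])
    top = water_topology(2)
    return coords, top, Box.cubic(20.0)


def random_water_frame(n_waters: int, box_length: float, seed: int):
    """Randomly placed and oriented rigid waters; returns (coords, topology, box)."""
    rng = np.random.default_rng(seed)
    o = rng.uniform(0, box_length, (n_waters, 3))
    axes = rng.standard_normal((n_waters, 3))
    hh = _rigid_water_h(axes)
    coords = np.empty((3 * n_waters, 3))
    coords[0::3] = o
    coords[1::3] = o + hh[0]
    coords[2::3] = o + hh[1]
    box = Box.cubic(box_length)
    return box.wrap(coords), water_topology(n_waters), box


@pytest.fixture
def tracer_trajectory():
    """5 tracers on deterministic straight-line paths, wrapped in a 10 Å box."""
    rng = np.random.default_rng(7)
    n, F = 5, 40
    r0 = rng.uniform(0, 10, (n, 3))
    v = rng.normal(0, 0.5, (n, 3))
    t = np.arange(F) * 0.1
    pos = r0[None] + v[None] * t[:, None, None]
    box = Box.cubic(10.0)
    top = Topology(
        elements=np.array(["O"] * n, dtype=object),
        masses=np.full(n, 15.999), charges=np.zeros(n),
        mol_ids=np.arange(n), roles=np.array(["ion"] * n, dtype=object),
    )
    wrapped = Trajectory(times=t, coords=box.wrap(pos), box=box, topology=top)
    return wrapped, pos
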