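"""Shared fixtures: small deterministic systems, generated at test time."""

from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

import chlorosim as cs


def make_site_geometry(positions, dipole_dirs, **kw):
    """Hand-built SiteGeometry for oracle tests."""
    positions = np.asarray(positions, float)
    dirs = np.asarray(dipole_dirs, float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    n = len(positions)
    return cs.SiteGeometry(
        positions=positions,
        dipole_dirs=dirs,
        axis=np.asarray(kw.get("axis", [0.0, 0.0, 1.0])),
        radius=float(kw.get("radius", 0.0)),
        stack_id=np.asarray(kw.get("stack_id", np.zeros(n, int))),
        sublattice=np.asarray(kw.get("sublattice", ["syn"] * n)),
        ring_index=np.asarray(kw.get("ring_index", np.arange(n))),
    )


@pytest.fixture(scope="session")
def parallel_dimer():
    """Two parallel z-dipoles stacked along z with J = -450 cm^-1 exactly."""
    from chlorosim.constants import DIPOLE_DEBYE, DIPOLE_PREFACTOR

    r = (2.0 * DIPOLE_PREFACTOR * DIPOLE_DEBYE**2 / 450.0) ** (1.0 / 3.0)
    g = make_site_geometry([[0, 0, 0], [0, 0, r]], [[0, 0, 1], [0, 0, 1]])
    return g


@pytest.fixture(scope="session")
def static_trimer():
    """Random-ish 3-site static system for sum-over-states oracles."""
    rng = np.random.default_rng(3)
    pos = rng.normal(scale=8.0, size=(3, 3))
    dirs = rng.normal(size=(3, 3))
    g = make_site_geometry(pos, dirs)
    diag = 15390.0 + rng.normal(scale=200.0, size=3)
    traj = cs.HamiltonianTrajectory(
        coupling=cs.coupling_matrix(g), diagonals=np.tile(diag, (80, 1)), dt=4.0
    )
    return g, traj


@pytest.fixture(scope="session")
def minitube():
    """~60-site wild-type cylinder with seeded default disorder."""
    geometry, disorder = cs.make_fixture("minitube", n_frames=300, seed=7)
    traj = cs.build_trajectory(geometry, disorder)
    return geometry, traj


@pytest.fixture(scope="session")
def wildtype_500():
    """N = 500 calibrated cylinder with a 20-frame default-disorder trajectory."""
    params = replace(cs.GeometryParams(), n_rings=25, n_per_ring=20)
    geometry = cs.build_wildtype_cylinder(params)
    disorder = cs.sample_disorder_trajectory(
        geometry.n_sites, cs.DisorderParams(n_frames=240, seed=1)
    )
    traj = cs.build_trajectory(geometry, disorder)
    return geometry, traj


@pytest.fixture(scope="session")
def wildtype_1000():
    """Full default wild-type geometry (N = 1000), geometry only."""
    return cs.build_wildtype_cylinder(cs.GeometryParams())
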