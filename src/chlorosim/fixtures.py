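"""Deterministic small systems used throughout the test suite and docs.

* ``monomer``  - one site at the origin, dipole along z, no couplings.
* ``dimer``    - an axial syn-anti stack pair on a near-flat wall; its
  single coupling sits at the calibrated nearest-neighbour value
  (about -450 cm^-1).
* ``ring6``    - six sites on a planar hexagon with dipoles normal to the
  ring plane; the Hamiltonian is circulant, so exact eigenvalues are
  available in closed form.
* ``minitube`` - a ~60-site wild-type cylinder (10 stacks of 6) with the
  calibrated lattice constants; the desk-scale stand-in for the full
  aggregate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .constants import DIPOLE_DEBYE
from .disorder import DisorderParams, DisorderTrajectory, sample_disorder_trajectory
from .geometry import GeometryParams, SiteGeometry, build_wildtype_cylinder

__all__ = ["FIXTURE_NAMES", "make_fixture", "fixture_geometry"]

FIXTURE_NAMES = ("monomer", "dimer", "ring6", "minitube")


def fixture_geometry(name: str) -> SiteGeometry:
    """Geometry of one named fixture system."""
    if name == "monomer":
        return SiteGeometry(
            positions=np.zeros((1, 3)),
            dipole_dirs=np.array([[0.0, 0.0, 1.0]]),
            axis=np.array([0.0, 0.0, 1.0]),
            radius=0.0,
            stack_id=np.zeros(1, dtype=int),
            sublattice=np.array(["syn"]),
            ring_index=np.zeros(1, dtype=int),
        )
    if name == "dimer":
        # Two consecutive stack sites; a huge radius flattens the wall so the
        # Mg-Mg separation equals the calibrated stack spacing essentially
        # exactly and the coupling lands on the nearest-neighbour peak value.
        params = replace(
            GeometryParams(), n_rings=2, n_per_ring=1, cylinder_radius=1.0e6
        )
        return build_wildtype_cylinder(params)
    if name == "ring6":
        k = np.arange(6)
        phi = 2.0 * np.pi * k / 6.0
        radius = 10.0  # Angstrom; nearest-neighbour distance = radius here
        return SiteGeometry(
            positions=np.stack(
                [radius * np.cos(phi), radius * np.sin(phi), np.zeros(6)], axis=1
            ),
            dipole_dirs=np.tile([0.0, 0.0, 1.0], (6, 1)),
            axis=np.array([0.0, 0.0, 1.0]),
            radius=radius,
            stack_id=np.zeros(6, dtype=int),
            sublattice=np.where(k % 2 == 0, "syn", "anti"),
            ring_index=k.copy(),
        )
    if name == "minitube":
        params = replace(GeometryParams(), n_rings=6, n_per_ring=10)
        return build_wildtype_cylinder(params)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(
    name: str,
    *,
    n_frames: int = 600,
    seed: int = 7,
    disorder: DisorderParams | None = None,
) -> tuple[SiteGeometry, DisorderTrajectory]:
    """Geometry plus a seeded disorder trajectory for one fixture system.

    The monomer, dimer and ring6 fixtures default to zero disorder (their
    role is closed-form validation); the minitube uses the default
    static + OU disorder model.
    """
    geometry = fixture_geometry(name)
    if disorder is None:
        if name == "minitube":
            disorder = DisorderParams(n_frames=n_frames, seed=seed)
        else:
            disorder = DisorderParams(
                sigma_static=0.0, sigma_dynamic=0.0, n_frames=n_frames, seed=seed
            )
    traj = sample_disorder_trajectory(geometry.n_sites, disorder)
    return geometry, traj
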