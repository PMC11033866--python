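"""One- and two-exciton Frenkel Hamiltonians.

Site basis: N two-level pigments with transition energies
``omega0 + Delta_omega_n(t)`` and point-dipole couplings ``J_mn``.  The
excitations are hard-core bosons (Paulions): a site cannot be doubly
excited, so the two-exciton manifold is spanned by the N(N-1)/2 pair states
|mn>, m < n, indexed lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DIPOLE_PREFACTOR, OMEGA0_CM
from .disorder import DisorderTrajectory
from .geometry import SiteGeometry

__all__ = [
    "HamiltonianFrame",
    "HamiltonianTrajectory",
    "TwoExcitonFrame",
    "point_dipole_coupling",
    "coupling_matrix",
    "build_frame",
    "build_trajectory",
    "two_exciton_frame",
    "pair_index_map",
]


@dataclass(frozen=True)
class HamiltonianFrame:
    """Symmetric one-exciton Hamiltonian (cm^-1) for one 4 fs time slice."""

    matrix: np.ndarray  # (N, N)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[0])


@dataclass(frozen=True)
class HamiltonianTrajectory:
    """Time-ordered one-exciton Hamiltonians at uniform spacing ``dt``.

    In the synthetic surrogate the couplings are static (the lattice does
    not move); only the diagonal fluctuates, so the trajectory is stored as
    a static coupling matrix plus the per-frame diagonal energies.
    """

    coupling: np.ndarray   # (N, N), zero diagonal, cm^-1
    diagonals: np.ndarray  # (n_frames, N), omega0 + Delta_omega_n(t), cm^-1
    dt: float              # fs

    @property
    def n_frames(self) -> int:
        return int(self.diagonals.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.diagonals.shape[1])

    def frame(self, index: int) -> HamiltonianFrame:
        if not 0 <= index < self.n_frames:
            raise IndexError(f"frame {index} outside [0, {self.n_frames})")
        m = self.coupling.copy()
        np.fill_diagonal(m, self.diagonals[index])
        return HamiltonianFrame(matrix=m)


def point_dipole_coupling(
    pos_m: np.ndarray,
    dir_m: np.ndarray,
    pos_n: np.ndarray,
    dir_n: np.ndarray,
    mu: float,
) -> float:
    """Point-dipole excitonic coupling in cm^-1.

    ``J = pref * mu^2 * [d_m.d_n - 3 (d_m.r)(d_n.r)] / r^3`` with the vacuum
    prefactor; positions in Angstrom, ``mu`` in Debye.  Distances below
    1 Angstrom are rejected as unphysical overlap (r = 0 raises its own
    error so coincident sites are reported distinctly).
    """
    r = np.asarray(pos_n, dtype=float) - np.asarray(pos_m, dtype=float)
    dist = float(np.linalg.norm(r))
    if dist == 0.0:
        raise ValueError("coincident sites (r = 0)")
    if dist < 1.0:
        raise ValueError(f"sites overlap (r = {dist:.3f} A < 1 A)")
    rh = r / dist
    dm = np.asarray(dir_m, dtype=float)
    dn = np.asarray(dir_n, dtype=float)
    kappa = float(dm @ dn - 3.0 * (dm @ rh) * (dn @ rh))
    return DIPOLE_PREFACTOR * mu * mu * kappa / dist**3


def coupling_matrix(geometry: SiteGeometry, cutoff: float | None = None) -> np.ndarray:
    """All-pairs point-dipole coupling matrix (cm^-1), zero diagonal.

    No distance cutoff by default: even distant, weakly coupled pairs are
    retained.  ``cutoff`` (Angstrom) zeroes couplings beyond that distance
    for speed; accuracy-sensitive work should leave it ``None``.
    """
    pos = geometry.positions
    dirs = geometry.dipole_dirs
    n = geometry.n_sites
    if n == 1:
        return np.zeros((1, 1))
    rvec = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(rvec, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if float(dist.min()) < 1.0:
        raise ValueError("geometry contains site pairs closer than 1 A")
    rhat = rvec / dist[..., None]
    ddot = dirs @ dirs.T
    proj = np.einsum("mi,mni->mn", dirs, rhat)       # d_m . rhat(m->n)
    proj_t = np.einsum("ni,mni->mn", dirs, rhat)     # d_n . rhat(m->n)
    kappa = ddot - 3.0 * proj * proj_t
    mu2 = geometry.dipole_magnitude**2
    J = DIPOLE_PREFACTOR * mu2 * kappa / dist**3
    if cutoff is not None:
        J = np.where(dist <= cutoff, J, 0.0)
    np.fill_diagonal(J, 0.0)
    return 0.5 * (J + J.T)  # symmetrize away float round-off


def build_frame(
    geometry: SiteGeometry,
    offsets: np.ndarray,
    *,
    coupling: np.ndarray | None = None,
    omega0: float = OMEGA0_CM,
) -> HamiltonianFrame:
    """Assemble one Hamiltonian frame from geometry and site-energy offsets."""
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (geometry.n_sites,):
        raise ValueError(
            f"offsets length {offsets.shape} does not match N = {geometry.n_sites}"
        )
    J = coupling_matrix(geometry) if coupling is None else coupling
    m = J.copy()
    np.fill_diagonal(m, omega0 + offsets)
    return HamiltonianFrame(matrix=m)


def build_trajectory(
    geometry: SiteGeometry,
    disorder: DisorderTrajectory,
    *,
    static_couplings: bool = True,
    omega0: float = OMEGA0_CM,
    cutoff: float | None = None,
) -> HamiltonianTrajectory:
    """One Hamiltonian frame per disorder frame.

    The synthetic lattice has no nuclear motion, so couplings are computed
    once from the fixed geometry (``static_couplings=True`` is the only
    supported mode; the flag is kept in the signature as the seam where
    fluctuating couplings would enter given positional trajectories).
    """
    if disorder.n_sites != geometry.n_sites:
        raise ValueError("disorder and geometry disagree on the number of sites")
    if not static_couplings:
        raise NotImplementedError(
            "fluctuating couplings require positional trajectories, which the "
            "synthetic surrogate does not produce"
        )
    J = coupling_matrix(geometry, cutoff=cutoff)
    return HamiltonianTrajectory(
        coupling=J, diagonals=omega0 + disorder.offsets, dt=disorder.dt
    )


# ----------------------------------------------------------------------------
# Two-exciton (pair) manifold
# ----------------------------------------------------------------------------


def pair_index_map(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Lexicographic bijection (m < n) <-> 0 .. N(N-1)/2 - 1.

    Returns arrays ``(ms, ns)`` with ``ms[p] < ns[p]`` such that pair ``p``
    is |ms[p], ns[p]>; the ordering is (0,1), (0,2), ..., (0,N-1), (1,2), ...
    """
    ms, ns = np.triu_indices(n, k=1)
    return ms, ns


@dataclass(frozen=True)
class TwoExcitonFrame:
    """Hard-core-boson pair-state Hamiltonian for one time slice.

    Diagonal entries are additive, ``<mn|H2|mn> = H1[m,m] + H1[n,n]``;
    off-diagonal entries inherit the one-exciton coupling of the differing
    index when exactly one index is shared, and vanish otherwise.
    """

    matrix: np.ndarray   # (P, P), P = N(N-1)/2
    n_sites: int

    @property
    def n_pairs(self) -> int:
        return int(self.matrix.shape[0])


def two_exciton_frame(frame: HamiltonianFrame) -> TwoExcitonFrame:
    """Build the pair-basis Hamiltonian from a one-exciton frame."""
    h1 = frame.matrix
    n = frame.n_sites
    if n < 2:
        raise ValueError("two-exciton manifold requires N >= 2")
    ms, ns = pair_index_map(n)
    p = len(ms)
    h2 = np.zeros((p, p))
    # Shared-index blocks: <mn|H2|m'n'> = H1 coupling of the differing sites.
    shared = (ms[:, None] == ms[None, :]).astype(bool)
    h2[shared] += h1[ns[:, None], ns[None, :]][shared]
    shared = ns[:, None] == ns[None, :]
    h2[shared] += h1[ms[:, None], ms[None, :]][shared]
    shared = ns[:, None] == ms[None, :]
    h2[shared] += h1[ms[:, None], ns[None, :]][shared]
    shared = ms[:, None] == ns[None, :]
    h2[shared] += h1[ns[:, None], ms[None, :]][shared]
    # The loop above double-counts the diagonal (two shared indices): fix it.
    np.fill_diagonal(h2, h1[ms, ms] + h1[ns, ns])
    return TwoExcitonFrame(matrix=h2, n_sites=n)
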