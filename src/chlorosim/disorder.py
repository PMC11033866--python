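"""Stochastic site-energy disorder.

The published model draws its transition-energy fluctuations from molecular
dynamics plus quantum chemistry; neither is public, so this module provides
a stochastic surrogate: per site, a static Gaussian offset (inhomogeneous
disorder) plus an Ornstein-Uhlenbeck process (dynamic disorder with a finite
correlation time), sampled exactly on the 4 fs Hamiltonian grid.

Seeding uses counter-based stream splitting: every (realization, site) pair
owns an independent child of the master ``SeedSequence``, so enlarging the
site count or the number of realizations never reshuffles earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DT_FS

__all__ = ["DisorderParams", "DisorderTrajectory", "sample_disorder_trajectory"]


@dataclass(frozen=True)
class DisorderParams:
    """Parameters of the static + Ornstein-Uhlenbeck site-energy model.

    ``sigma_static`` and ``sigma_dynamic`` are standard deviations in cm^-1
    of the frozen offset and of the stationary OU distribution respectively;
    ``tau_corr`` is the OU autocorrelation time in fs.  Defaults are
    order-of-magnitude choices producing a broad, partly inhomogeneous
    exciton band; the source model does not print its disorder magnitudes.
    """

    sigma_static: float = 300.0
    sigma_dynamic: float = 400.0
    tau_corr: float = 50.0
    dt: float = DT_FS
    n_frames: int = 250
    seed: int = 0
    realization: int = 0

    def __post_init__(self) -> None:
        if self.sigma_static < 0 or self.sigma_dynamic < 0:
            raise ValueError("disorder sigmas must be >= 0")
        if self.tau_corr <= 0:
            raise ValueError("tau_corr must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class DisorderTrajectory:
    """Per-site transition-energy offsets on a uniform time grid."""

    offsets: np.ndarray  # (n_frames, n_sites), cm^-1
    dt: float            # fs

    @property
    def n_frames(self) -> int:
        return int(self.offsets.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.offsets.shape[1])


def _site_rng(seed: int, realization: int, site: int) -> np.random.Generator:
    """Independent stream for one (realization, site) pair."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(realization, site))
    )


def sample_disorder_trajectory(n_sites: int, params: DisorderParams) -> DisorderTrajectory:
    """Draw ``offset_n(t) = s_n + d_n(t)`` for every site.

    ``s_n ~ N(0, sigma_static^2)`` is drawn once per site; ``d_n(t)`` is an
    Ornstein-Uhlenbeck process with stationary variance ``sigma_dynamic^2``
    and autocovariance ``sigma_dynamic^2 * exp(-|t|/tau_corr)``, advanced
    with the exact discrete-time transition

        d_{k+1} = rho * d_k + sqrt(1 - rho^2) * sigma_dynamic * xi_k,
        rho = exp(-dt / tau_corr),

    so the sampled process is exact at any step size.  Sites are independent
    and individually seeded (see module docstring).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    p = params
    rho = math.exp(-p.dt / p.tau_corr)
    q = math.sqrt(1.0 - rho * rho)

    offsets = np.empty((p.n_frames, n_sites))
    for site in range(n_sites):
        rng = _site_rng(p.seed, p.realization, site)
        static = rng.normal(0.0, p.sigma_static) if p.sigma_static > 0 else 0.0
        if p.sigma_dynamic > 0:
            xi = rng.normal(size=p.n_frames)
            d = np.empty(p.n_frames)
            d[0] = p.sigma_dynamic * xi[0]  # start in the stationary state
            for k in range(1, p.n_frames):
                d[k] = rho * d[k - 1] + q * p.sigma_dynamic * xi[k]
        else:
            d = np.zeros(p.n_frames)
        offsets[:, site] = static + d
    return DisorderTrajectory(offsets=offsets, dt=p.dt)
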