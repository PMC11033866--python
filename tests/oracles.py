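"""Independent oracles used by the test suite.

Everything here is deliberately written *against different primitives* than
the package: brute-force enumeration of the full hard-core-boson space,
dense matrix exponentials, sum-over-states response functions from exact
eigenstates, and Monte-Carlo orientational averaging.  They validate the
production code paths without sharing them.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from chlorosim.constants import PHASE_PER_CM_FS
from chlorosim.hamiltonian import HamiltonianFrame, pair_index_map, two_exciton_frame


def paulion_two_exciton_bruteforce(h1: np.ndarray) -> np.ndarray:
    """Two-excitation sector of the full 2^N hard-core boson Hamiltonian.

    Enumerates all occupation bitstrings with exactly two excitations and
    applies H = sum_n h_nn B_n^+ B_n + sum_{m!=n} h_mn B_m^+ B_n directly,
    then maps onto the package's lexicographic pair ordering.
    """
    n = h1.shape[0]
    states = [frozenset(c) for c in itertools.combinations(range(n), 2)]
    index = {s: i for i, s in enumerate(states)}
    dim = len(states)
    h2 = np.zeros((dim, dim))
    for s, i in index.items():
        occ = sorted(s)
        h2[i, i] = sum(h1[k, k] for k in occ)
        for m in range(n):
            for k in occ:
                if m == k or m in s:
                    continue
                target = frozenset(s - {k} | {m})
                h2[index[target], i] += h1[m, k]
    ms, ns = pair_index_map(n)
    order = [index[frozenset((m, k))] for m, k in zip(ms, ns)]
    return h2[np.ix_(order, order)]


def expm_propagator(h: np.ndarray, t_fs: float) -> np.ndarray:
    """Dense matrix-exponential propagator (scipy) as an oracle."""
    return expm(-1j * PHASE_PER_CM_FS * np.asarray(h, dtype=complex) * t_fs)


def sos_pathway_tensor(
    h: np.ndarray,
    mu_site: np.ndarray,
    pathway: str,
    phase: str,
    n1: int,
    n3: int,
    k2: int,
    dt: float,
) -> np.ndarray:
    """Sum-over-states third-order pathway tensor for a *static* Hamiltonian.

    Returns shape (n1, n3, 3, 3, 3, 3); trailing axes are the Cartesian
    components of the four interactions in time order.
    """
    N = h.shape[0]
    E, C = np.linalg.eigh(h)
    m = C.T @ mu_site
    t1 = np.arange(n1) * dt
    t3 = np.arange(n3) * dt
    t2 = k2 * dt
    ph = PHASE_PER_CM_FS
    out = np.zeros((n1, n3, 3, 3, 3, 3), complex)

    if pathway == "GSB":
        for k in range(N):
            for l in range(N):
                sgn = +1 if phase == "rephasing" else -1
                amp = np.exp(sgn * 1j * ph * E[k] * t1)[:, None] * np.exp(
                    -1j * ph * E[l] * t3
                )[None, :]
                tens = np.einsum("a,b,c,d->abcd", m[k], m[k], m[l], m[l])
                out += amp[:, :, None, None, None, None] * tens
        return out

    if pathway == "SE":
        for k in range(N):
            for l in range(N):
                if phase == "rephasing":
                    amp = (
                        np.exp(+1j * ph * E[k] * t1)[:, None]
                        * np.exp(-1j * ph * E[l] * t3)[None, :]
                        * np.exp(+1j * ph * (E[k] - E[l]) * t2)
                    )
                    tens = np.einsum("a,b,c,d->abcd", m[k], m[l], m[k], m[l])
                else:
                    amp = (
                        np.exp(-1j * ph * E[k] * t1)[:, None]
                        * np.exp(-1j * ph * E[k] * t3)[None, :]
                        * np.exp(-1j * ph * (E[k] - E[l]) * t2)
                    )
                    tens = np.einsum("a,b,c,d->abcd", m[k], m[l], m[l], m[k])
                out += amp[:, :, None, None, None, None] * tens
        return out

    if pathway != "ESA":
        raise ValueError(pathway)
    if N < 2:
        return out
    h2 = two_exciton_frame(HamiltonianFrame(np.asarray(h, float))).matrix
    F, Cq = np.linalg.eigh(h2)
    ms, ns = pair_index_map(N)
    P = len(ms)
    mu12 = np.zeros((3, P, N))
    for a in range(3):
        for p in range(P):
            mu12[a, p, ns[p]] += mu_site[ms[p], a]
            mu12[a, p, ms[p]] += mu_site[ns[p], a]
    M = np.einsum("pq,apn,nk->qka", Cq, mu12, C)
    for k in range(N):
        for l in range(N):
            for q in range(P):
                if phase == "rephasing":
                    amp = (
                        np.exp(+1j * ph * E[k] * t1)[:, None]
                        * np.exp(+1j * ph * (E[k] - F[q]) * t3)[None, :]
                        * np.exp(+1j * ph * (E[k] - E[l]) * t2)
                    )
                    tens = np.einsum(
                        "a,b,c,d->abcd", m[k], m[l], M[q, l], M[q, k]
                    )
                else:
                    amp = (
                        np.exp(-1j * ph * E[k] * t1)[:, None]
                        * np.exp(+1j * ph * (E[l] - F[q]) * t3)[None, :]
                        * np.exp(-1j * ph * (E[k] - E[l]) * t2)
                    )
                    tens = np.einsum(
                        "a,b,c,d->abcd", m[k], m[l], M[q, k], M[q, l]
                    )
                out -= amp[:, :, None, None, None, None] * tens
    return out


def mc_parallel_average(dipole_tensor_fn, n_samples: int, seed: int) -> complex:
    """Monte-Carlo isotropic <xxxx> average over random lab orientations.

    ``dipole_tensor_fn`` maps nothing -> (3,3,3,3) molecular-frame tensor;
    the average of x-projections over uniformly random rotations estimates
    the analytic fourth-rank contraction.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    tensor = dipole_tensor_fn()
    total = 0.0
    rots = Rotation.random(n_samples, random_state=rng).as_matrix()
    x = rots[:, 0, :]  # lab x-axis in molecular frame, (n, 3)
    total = np.einsum("na,nb,nc,nd,abcd->", x, x, x, x, tensor) / n_samples
    return total
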