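"""Static exciton-band analysis.

Per-frame diagonalization of the one-exciton Hamiltonian and the derived
band observables: density of states, participation ratio (number-of-sites
convention: PR = 1 for a fully localized state, N for a uniform one),
oscillator strength f = |mu_k|^2, the pairwise coupling distribution with
peak location/assignment, dipole-axis angle statistics, and a report on the
low-lying dark-type states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SiteGeometry, dipole_axis_angles_deg
from .hamiltonian import HamiltonianFrame, coupling_matrix

__all__ = [
    "ExcitonStates",
    "BandReport",
    "diagonalize_frame",
    "participation_ratio",
    "coupling_histogram",
    "nn_peak_center",
    "nnn_peak_centers",
    "dipole_axis_angles",
    "dark_state_report",
    "band_report",
]

#: Cap applied to f-ratios so reports stay finite for truly dark states.
F_RATIO_CAP = 1e6


@dataclass(frozen=True)
class ExcitonStates:
    """Eigenstates of one Hamiltonian frame, sorted by energy."""

    energies: np.ndarray       # (N,) cm^-1, ascending
    coefficients: np.ndarray   # (N, N); column k is state k over sites
    state_dipoles: np.ndarray  # (N, 3) Debye
    oscillator_strengths: np.ndarray  # (N,) Debye^2
    participation_ratios: np.ndarray  # (N,) in [1, N]

    @property
    def n_states(self) -> int:
        return int(self.energies.size)


def participation_ratio(coefficients: np.ndarray) -> float | np.ndarray:
    """PR = (sum |c|^2)^2 / sum |c|^4 for one state vector or stacked columns.

    Dimensionless effective number of sites the state occupies; raises on a
    zero vector.
    """
    c = np.asarray(coefficients)
    c2 = np.abs(c) ** 2
    norm = c2.sum(axis=0)
    if np.any(norm == 0):
        raise ValueError("zero state vector has no participation ratio")
    pr = norm**2 / (c2**2).sum(axis=0)
    return float(pr) if np.isscalar(pr) or pr.ndim == 0 else pr


def diagonalize_frame(frame: HamiltonianFrame, geometry: SiteGeometry) -> ExcitonStates:
    """Eigenstates with per-state dipoles, oscillator strengths and PRs."""
    h = frame.matrix
    if not np.allclose(h, h.T, atol=1e-8):
        raise ValueError("Hamiltonian frame must be symmetric")
    energies, coeff = np.linalg.eigh(h)
    mu_states = coeff.T @ geometry.dipoles()          # (N, 3)
    f = np.einsum("ki,ki->k", mu_states, mu_states)
    return ExcitonStates(
        energies=energies,
        coefficients=coeff,
        state_dipoles=mu_states,
        oscillator_strengths=f,
        participation_ratios=participation_ratio(coeff),
    )


# ----------------------------------------------------------------------------
# Coupling distribution
# ----------------------------------------------------------------------------

#: Bin width of the coupling histogram (cm^-1).
COUPLING_BIN_WIDTH = 20.0
#: Couplings with |J| below this belong to the central distant-pair peak.
COUPLING_ZERO_REGION = 50.0
#: Minimum peak prominence as a fraction of the tallest non-zero-region bin.
COUPLING_PROMINENCE = 0.05


@dataclass(frozen=True)
class CouplingPeak:
    center: float       # count-weighted mean coupling of the peak's bins, cm^-1
    height: int         # count in the apex bin
    assignment: str     # 'same-stack-nn' | 'inter-stack' | 'other'


def _pair_classes(geometry: SiteGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle masks for same-stack nearest-neighbour and inter-stack pairs."""
    ms, ns = np.triu_indices(geometry.n_sites, k=1)
    same_stack = geometry.stack_id[ms] == geometry.stack_id[ns]
    nn = same_stack & (np.abs(geometry.ring_index[ms] - geometry.ring_index[ns]) == 1)
    n_stacks = int(geometry.stack_id.max()) + 1
    dj = np.abs(geometry.stack_id[ms] - geometry.stack_id[ns])
    adjacent_stack = (dj == 1) | (dj == n_stacks - 1)  # periodic around the tube
    return nn, adjacent_stack


def coupling_histogram(
    geometry: SiteGeometry,
    bin_width: float = COUPLING_BIN_WIDTH,
) -> tuple[np.ndarray, np.ndarray, list[CouplingPeak]]:
    """Histogram of all N(N-1)/2 couplings plus located non-central peaks.

    Returns ``(bin_edges, counts, peaks)``.  Peak finding: bins strictly
    exceeding both neighbours with height at least 5 percent of the tallest
    bin outside the central |J| < 50 cm^-1 region; the central distant-pair
    peak itself is excluded.  Each peak's centre is the count-weighted mean
    coupling over its flanks (contiguous bins descending from the apex) and
    is assigned to the dominant structural pair class among same-stack
    nearest neighbours and inter-stack (adjacent-stack) pairs.
    """
    n = geometry.n_sites
    if n < 2:
        raise ValueError("coupling histogram requires N >= 2")
    J = coupling_matrix(geometry)
    ms, ns = np.triu_indices(n, k=1)
    vals = J[ms, ns]
    # pad one empty bin on each side so extreme coupling classes still
    # register as local maxima
    lo = np.floor(vals.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    outside = np.abs(centers) >= COUPLING_ZERO_REGION
    if not outside.any() or counts[outside].max() == 0:
        return edges, counts, []
    threshold = COUPLING_PROMINENCE * counts[outside].max()

    nn_mask, inter_mask = _pair_classes(geometry)
    which = np.digitize(vals, edges) - 1

    peaks: list[CouplingPeak] = []
    for b in range(1, len(counts) - 1):
        if not outside[b]:
            continue
        if counts[b] < threshold:
            continue
        if not (counts[b] > counts[b - 1] and counts[b] >= counts[b + 1]):
            continue
        # flanks: walk down while counts decrease, staying off the zero region
        left = b
        while left - 1 >= 0 and counts[left - 1] < counts[left] and outside[left - 1]:
            left -= 1
        right = b
        while (
            right + 1 < len(counts)
            and counts[right + 1] < counts[right]
            and outside[right + 1]
        ):
            right += 1
        sel = (which >= left) & (which <= right)
        if not sel.any():
            continue
        center = float(vals[sel].mean())
        n_nn = int((sel & nn_mask).sum())
        n_inter = int((sel & inter_mask).sum())
        n_other = int(sel.sum()) - n_nn - n_inter
        assignment = ["same-stack-nn", "inter-stack", "other"][
            int(np.argmax([n_nn, n_inter, n_other]))
        ]
        peaks.append(CouplingPeak(center=center, height=int(counts[b]), assignment=assignment))
    return edges, counts, peaks


def nn_peak_center(peaks: list[CouplingPeak]) -> float:
    """Centre of the nearest-neighbour (same-stack) coupling peak.

    The strongest-coupling same-stack peak, i.e. the one farthest from zero.
    """
    cands = [p.center for p in peaks if p.assignment == "same-stack-nn"]
    if not cands:
        raise ValueError("no same-stack nearest-neighbour peak found")
    return max(cands, key=abs)


def nnn_peak_centers(peaks: list[CouplingPeak]) -> tuple[float, float]:
    """(positive, negative) centres of the two inter-stack coupling peaks.

    The two next-nearest-neighbour classes are the strongest inter-stack
    couplings of each sign, i.e. the most positive and most negative
    inter-stack-assigned peak centres.
    """
    inter = [p.center for p in peaks if p.assignment == "inter-stack"]
    pos = [c for c in inter if c > 0]
    neg = [c for c in inter if c < 0]
    if not pos or not neg:
        raise ValueError("missing an inter-stack peak of one sign")
    return max(pos), min(neg)


def dipole_axis_angles(geometry: SiteGeometry, bin_width: float = 2.0):
    """Distribution of dipole-axis angles folded to [0, 90] deg.

    Returns ``(angles_deg, mean_deg, (bin_edges, counts))``.
    """
    if geometry.n_sites < 1:
        raise ValueError("empty geometry")
    angles = dipole_axis_angles_deg(geometry)
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    return angles, float(angles.mean()), (edges, counts)


# ----------------------------------------------------------------------------
# Dark-state reporting
# ----------------------------------------------------------------------------


def dark_state_report(states: ExcitonStates, n_low: int = 10) -> pd.DataFrame:
    """Table of the ``n_low`` lowest states with dark-type flags.

    Columns: energy, oscillator strength, PR, ratio of the global maximum
    oscillator strength to the state's (capped at 1e6), and a boolean
    ``dark_multichromophoric`` marking states that are both delocalized
    (PR >= 2) and at least 10x weaker than the brightest state.
    """
    if states.n_states < n_low:
        raise ValueError(f"need at least {n_low} states, got {states.n_states}")
    f_max = float(states.oscillator_strengths.max())
    f = states.oscillator_strengths[:n_low]
    with np.errstate(divide="ignore"):
        ratio = np.where(f > 0, f_max / np.maximum(f, f_max / F_RATIO_CAP), F_RATIO_CAP)
    pr = states.participation_ratios[:n_low]
    return pd.DataFrame(
        {
            "energy_cm": states.energies[:n_low],
            "oscillator_strength_D2": f,
            "participation_ratio": pr,
            "f_ratio_to_max": np.minimum(ratio, F_RATIO_CAP),
            "dark_multichromophoric": (pr >= 2.0) & (ratio >= 10.0),
        }
    )


@dataclass
class BandReport:
    """Aggregated band analysis over one or more frames."""

    dos_edges: np.ndarray
    dos_counts: np.ndarray
    states_table: pd.DataFrame       # per (frame, state): energy, f, PR
    coupling_edges: np.ndarray
    coupling_counts: np.ndarray
    coupling_peaks: list
    angle_mean_deg: float
    angle_edges: np.ndarray
    angle_counts: np.ndarray
    dark_states: pd.DataFrame
    n_frames: int = 1


def band_report(
    geometry: SiteGeometry,
    frames: list[HamiltonianFrame],
    *,
    dos_bin_width: float = 50.0,
    n_low: int = 10,
) -> BandReport:
    """Full band analysis, ensemble-averaged over the supplied frames.

    The DOS histogram and the (energy, f, PR) table pool all frames; the
    dark-state table is taken from the first frame (a representative
    snapshot, as a per-frame property).
    """
    if not frames:
        raise ValueError("need at least one frame")
    all_states = [diagonalize_frame(fr, geometry) for fr in frames]
    energies = np.concatenate([s.energies for s in all_states])
    lo = np.floor(energies.min() / dos_bin_width) * dos_bin_width
    hi = np.ceil(energies.max() / dos_bin_width) * dos_bin_width + dos_bin_width
    dos_edges = np.arange(lo, hi, dos_bin_width)
    dos_counts, _ = np.histogram(energies, bins=dos_edges)
    table = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(len(frames)), geometry.n_sites),
            "energy_cm": energies,
            "oscillator_strength_D2": np.concatenate(
                [s.oscillator_strengths for s in all_states]
            ),
            "participation_ratio": np.concatenate(
                [s.participation_ratios for s in all_states]
            ),
        }
    )
    c_edges, c_counts, c_peaks = coupling_histogram(geometry)
    _, angle_mean, (a_edges, a_counts) = dipole_axis_angles(geometry)
    dark = dark_state_report(all_states[0], n_low=n_low)
    return BandReport(
        dos_edges=dos_edges,
        dos_counts=dos_counts,
        states_table=table,
        coupling_edges=c_edges,
        coupling_counts=c_counts,
        coupling_peaks=c_peaks,
        angle_mean_deg=angle_mean,
        angle_edges=a_edges,
        angle_counts=a_counts,
        dark_states=dark,
        n_frames=len(frames),
    )
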