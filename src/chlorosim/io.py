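"""File formats.

* Geometry: extended XYZ - the element column carries the syn/anti label,
  the comment line carries axis, radius and dipole magnitude as key=value
  pairs, and per-site columns hold position, dipole direction, stack id and
  ring index.
* Disorder / Hamiltonian trajectories: a flat little-endian binary container
  (8-byte magic, int64 sizes, float64 payload) with an equivalent
  whitespace text dialect for small systems; readers auto-detect.
* Spectra: long-format TSV (omega1, omega3, amplitude, t2, pathway);
  time traces as two-column TSV.
"""

from __future__ import annotations

import gzip
import io as _io
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .disorder import DisorderTrajectory
from .geometry import SiteGeometry
from .hamiltonian import HamiltonianTrajectory
from .spectroscopy import Spectrum2D, TimeTrace

__all__ = [
    "write_geometry_xyz",
    "read_geometry_xyz",
    "write_disorder",
    "read_disorder",
    "write_hamiltonian",
    "read_hamiltonian",
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_trace_tsv",
]

_DIS_MAGIC = b"CHLSDIS1"
_HAM_MAGIC = b"CHLSHAM1"


# ----------------------------------------------------------------------------
# Geometry (extended XYZ)
# ----------------------------------------------------------------------------


def write_geometry_xyz(geometry: SiteGeometry, path: str | Path) -> None:
    g = geometry
    ax = g.axis
    header = (
        f'axis="{ax[0]:.12g} {ax[1]:.12g} {ax[2]:.12g}" '
        f"radius={g.radius:.12g} dipole_magnitude={g.dipole_magnitude:.12g} "
        'Properties=species:S:1:pos:R:3:dipole:R:3:stack:I:1:ring:I:1'
    )
    lines = [str(g.n_sites), header]
    for i in range(g.n_sites):
        p, d = g.positions[i], g.dipole_dirs[i]
        lines.append(
            f"{g.sublattice[i]} "
            f"{p[0]:.10f} {p[1]:.10f} {p[2]:.10f} "
            f"{d[0]:.12f} {d[1]:.12f} {d[2]:.12f} "
            f"{int(g.stack_id[i])} {int(g.ring_index[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_geometry_xyz(path: str | Path) -> SiteGeometry:
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0])
    meta: dict[str, str] = {}
    comment = text[1]
    # parse key=value with possible quoted values
    pos = 0
    while pos < len(comment):
        eq = comment.find("=", pos)
        if eq < 0:
            break
        key = comment[pos:eq].strip().split()[-1]
        rest = comment[eq + 1 :]
        if rest.startswith('"'):
            end = rest.find('"', 1)
            val, pos = rest[1:end], eq + 2 + end
        else:
            end = rest.find(" ")
            if end < 0:
                end = len(rest)
            val, pos = rest[:end], eq + 1 + end
        meta[key] = val
    rows = [ln.split() for ln in text[2 : 2 + n]]
    if len(rows) != n:
        raise ValueError(f"expected {n} site rows, found {len(rows)}")
    sub = np.array([r[0] for r in rows])
    dat = np.array([[float(x) for x in r[1:7]] for r in rows])
    ints = np.array([[int(r[7]), int(r[8])] for r in rows])
    return SiteGeometry(
        positions=dat[:, 0:3],
        dipole_dirs=dat[:, 3:6] / np.linalg.norm(dat[:, 3:6], axis=1, keepdims=True),
        axis=np.array([float(x) for x in meta["axis"].split()]),
        radius=float(meta["radius"]),
        stack_id=ints[:, 0],
        sublattice=sub,
        ring_index=ints[:, 1],
        dipole_magnitude=float(meta["dipole_magnitude"]),
    )


# ----------------------------------------------------------------------------
# Flat binary container (+ text dialect) for disorder and Hamiltonians
# ----------------------------------------------------------------------------


def write_disorder(traj: DisorderTrajectory, path: str | Path, *, text: bool = False) -> None:
    """Flat binary by default; ``text=True`` writes the TSV dialect
    (gzipped when the path ends in .gz)."""
    path = Path(path)
    if text or path.suffix == ".gz":
        buf = _io.StringIO()
        buf.write(f"# CHLSDIS1 text n_sites={traj.n_sites} n_frames={traj.n_frames} dt={traj.dt}\n")
        np.savetxt(buf, traj.offsets, fmt="%.10g", delimiter="\t")
        data = buf.getvalue().encode()
        if path.suffix == ".gz":
            path.write_bytes(gzip.compress(data))
        else:
            path.write_bytes(data)
        return
    with open(path, "wb") as fh:
        fh.write(_DIS_MAGIC)
        fh.write(struct.pack("<qqd", traj.n_sites, traj.n_frames, traj.dt))
        fh.write(np.ascontiguousarray(traj.offsets, dtype="<f8").tobytes())


def read_disorder(path: str | Path) -> DisorderTrajectory:
    path = Path(path)
    raw = path.read_bytes()
    if path.suffix == ".gz":
        raw = gzip.decompress(raw)
    if raw.startswith(_DIS_MAGIC):
        n, nf, dt = struct.unpack_from("<qqd", raw, 8)
        offs = np.frombuffer(raw, dtype="<f8", offset=8 + 24).reshape(nf, n).copy()
        return DisorderTrajectory(offsets=offs, dt=dt)
    # text dialect
    lines = raw.decode().strip().splitlines()
    head = dict(tok.split("=") for tok in lines[0].split() if "=" in tok)
    offs = np.loadtxt(_io.StringIO("\n".join(lines[1:])), ndmin=2)
    if offs.shape != (int(head["n_frames"]), int(head["n_sites"])):
        raise ValueError("disorder text header disagrees with table shape")
    return DisorderTrajectory(offsets=offs, dt=float(head["dt"]))


def write_hamiltonian(traj: HamiltonianTrajectory, path: str | Path, *, text: bool = False) -> None:
    """Frame-major lower-triangle storage of every frame.

    Binary: magic, N, n_frames, dt, then n_frames blocks of N(N+1)/2
    float64 (row-major lower triangle including the diagonal).  The text
    dialect (one frame per line) is intended for small N.
    """
    n = traj.n_sites
    il = np.tril_indices(n)
    frames = np.stack(
        [traj.frame(k).matrix[il] for k in range(traj.n_frames)], axis=0
    )
    path = Path(path)
    if text:
        with open(path, "w") as fh:
            fh.write(f"# CHLSHAM1 text n_sites={n} n_frames={traj.n_frames} dt={traj.dt}\n")
            np.savetxt(fh, frames, fmt="%.10g", delimiter="\t")
        return
    with open(path, "wb") as fh:
        fh.write(_HAM_MAGIC)
        fh.write(struct.pack("<qqd", n, traj.n_frames, traj.dt))
        fh.write(np.ascontiguousarray(frames, dtype="<f8").tobytes())


def read_hamiltonian(path: str | Path) -> HamiltonianTrajectory:
    """Auto-detecting reader for the binary and text dialects.

    Off-diagonal (coupling) entries are taken from the first frame; the
    stored per-frame diagonals are kept exactly (the package's trajectory
    model carries static couplings and fluctuating site energies).
    """
    raw = Path(path).read_bytes()
    if raw.startswith(_HAM_MAGIC):
        n, nf, dt = struct.unpack_from("<qqd", raw, 8)
        frames = np.frombuffer(raw, dtype="<f8", offset=8 + 24).reshape(
            nf, n * (n + 1) // 2
        )
    else:
        lines = raw.decode().strip().splitlines()
        head = dict(tok.split("=") for tok in lines[0].split() if "=" in tok)
        n, nf, dt = int(head["n_sites"]), int(head["n_frames"]), float(head["dt"])
        frames = np.loadtxt(_io.StringIO("\n".join(lines[1:])), ndmin=2)
    il = np.tril_indices(n)
    first = np.zeros((n, n))
    first[il] = frames[0]
    coupling = first + first.T
    np.fill_diagonal(coupling, 0.0)
    diag_cols = np.where(il[0] == il[1])[0]
    diagonals = frames[:, diag_cols].copy()
    return HamiltonianTrajectory(coupling=coupling, diagonals=diagonals, dt=dt)


# ----------------------------------------------------------------------------
# Spectra and traces
# ----------------------------------------------------------------------------


def write_spectrum_tsv(
    spectrum: Spectrum2D, path: str | Path, *, pathway: str | None = None
) -> None:
    o1, o3 = np.meshgrid(spectrum.omega1, spectrum.omega3, indexing="ij")
    df = pd.DataFrame(
        {
            "omega1_cm": o1.ravel(),
            "omega3_cm": o3.ravel(),
            "amplitude": spectrum.amplitude.ravel(),
            "t2_fs": spectrum.t2,
            "pathway": pathway or "+".join(spectrum.pathways),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_spectrum_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trace_tsv(trace: TimeTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# omega1={trace.omega1} omega3={trace.omega3} (cm^-1)\n")
        fh.write("t2_fs\tamplitude\n")
        for t, a in zip(trace.t2, trace.amplitude):
            fh.write(f"{t:.6g}\t{a:.10g}\n")
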