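"""Run configuration and pipeline orchestration.

``RunConfig`` is a schema-validated (pydantic, unknown keys rejected) YAML
configuration mirroring the geometry, disorder and spectroscopy parameter
sets plus analysis options and output paths.  ``run_pipeline`` executes the
stages build -> hamiltonian -> spectra -> analysis, skipping stages whose
outputs already exist under a matching configuration hash, and writes a
manifest recording seeds, versions and output hashes next to the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _version
from .constants import DT_FS
from .disorder import DisorderParams, sample_disorder_trajectory
from .geometry import GeometryParams, build_wildtype_cylinder

log = logging.getLogger("chlorosim")

__all__ = ["RunConfig", "load_config", "run_pipeline", "PipelineError"]


class GeometrySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chiral_angle_delta: float = GeometryParams.chiral_angle_delta
    stack_spacing: float = GeometryParams.stack_spacing
    interstack_spacing: float = GeometryParams.interstack_spacing
    dipole_polar_tilt: float = GeometryParams.dipole_polar_tilt
    dipole_azimuth_syn: float = GeometryParams.dipole_azimuth_syn
    dipole_azimuth_anti: float = GeometryParams.dipole_azimuth_anti
    n_rings: int = 50
    n_per_ring: int = 20
    cylinder_radius: float | None = None

    def to_params(self) -> GeometryParams:
        return GeometryParams(**self.model_dump())


class DisorderSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_static: float = 300.0
    sigma_dynamic: float = 400.0
    tau_corr: float = 50.0
    dt: float = DT_FS
    n_frames: int = 600

    def to_params(self, seed: int) -> DisorderParams:
        return DisorderParams(seed=seed, **self.model_dump())


class SpectroscopySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t1_max: float = 196.0
    t3_max: float = 196.0
    coherence_step: float = DT_FS
    t2_list: list[float] = Field(default_factory=lambda: [float(t) for t in range(0, 481, 24)])
    apod_tau: float = 300.0
    zero_pad_factor: int = 4
    n_realizations: int = 10
    realization_stride: int = 250
    pathway_mask: list[str] = Field(default_factory=lambda: ["GSB", "SE", "ESA"])
    polarization: str = "isotropic"
    linear_t_max: float = 1000.0

    def to_config(self):
        from .spectroscopy import SpectroscopyConfig

        d = self.model_dump()
        d.pop("linear_t_max")
        d["t2_list"] = tuple(d["t2_list"])
        d["pathway_mask"] = tuple(d["pathway_mask"])
        return SpectroscopyConfig(**d)


class AnalysisSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_frames: int = 5
    n_low: int = 10
    dos_bin_width: float = 50.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 1
    out_dir: str = "chlorosim_run"
    log_level: str = "INFO"
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    disorder: DisorderSection = Field(default_factory=DisorderSection)
    spectroscopy: SpectroscopySection = Field(default_factory=SpectroscopySection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


class PipelineError(RuntimeError):
    """A stage dependency is missing or an intermediate file is corrupt."""


STAGES = ("build", "hamiltonian", "spectra", "analysis")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = STAGES, *, out_dir: str | Path | None = None
) -> dict:
    """Execute the pipeline stages in order; returns the manifest dict.

    Stage outputs land in ``config.out_dir`` (or ``out_dir`` override)
    together with the fully-resolved config and a manifest.  A stage whose
    outputs already exist under the current config hash is skipped; a
    missing or corrupt upstream file raises :class:`PipelineError` naming
    the stage to re-run.
    """
    from . import analysis as ana
    from . import io as cio
    from .hamiltonian import build_trajectory
    from .spectroscopy import linear_response, point_trace, twodes_spectrum

    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False)
    )

    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "version": _version, "seed": config.seed, "stages": {}}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == chash:
                manifest["stages"] = old.get("stages", {})
        except (json.JSONDecodeError, OSError):
            pass

    geom_path = out / "geometry.xyz"
    dis_path = out / "disorder.bin"
    ham_path = out / "hamiltonian.bin"

    def stage_done(name: str, outputs: list[Path]) -> bool:
        rec = manifest["stages"].get(name)
        if rec is None:
            return False
        for p in outputs:
            if not p.exists() or _file_hash(p) != rec["outputs"].get(p.name):
                return False
        return True

    def record(name: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][name] = {
            "outputs": {p.name: _file_hash(p) for p in outputs},
            "wall_time_s": round(time.time() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        log.info("stage %s done in %.2f s", name, time.time() - t0)

    def require(name: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists():
                raise PipelineError(
                    f"stage '{name}' requires {p.name}; re-run the producing stage"
                )

    if "build" in stages:
        outs = [geom_path, dis_path]
        if not stage_done("build", outs):
            t0 = time.time()
            geometry = build_wildtype_cylinder(config.geometry.to_params())
            cio.write_geometry_xyz(geometry, geom_path)
            disorder = sample_disorder_trajectory(
                geometry.n_sites, config.disorder.to_params(config.seed)
            )
            cio.write_disorder(disorder, dis_path)
            record("build", outs, t0)
        else:
            log.info("stage build skipped (up to date)")

    if "hamiltonian" in stages:
        require("hamiltonian", geom_path, dis_path)
        outs = [ham_path]
        if not stage_done("hamiltonian", outs):
            t0 = time.time()
            try:
                geometry = cio.read_geometry_xyz(geom_path)
                disorder = cio.read_disorder(dis_path)
            except (ValueError, KeyError, IndexError) as exc:
                raise PipelineError(
                    "stage 'hamiltonian': corrupt input file; re-run 'build'"
                ) from exc
            traj = build_trajectory(geometry, disorder)
            cio.write_hamiltonian(traj, ham_path)
            record("hamiltonian", outs, t0)
        else:
            log.info("stage hamiltonian skipped (up to date)")

    if "spectra" in stages:
        require("spectra", geom_path, ham_path)
        spec_cfg = config.spectroscopy.to_config()
        outs = [out / "absorption.tsv"] + [
            out / f"spectrum2d_t2_{int(t2):04d}.tsv" for t2 in spec_cfg.t2_list
        ]
        if not stage_done("spectra", outs):
            t0 = time.time()
            try:
                geometry = cio.read_geometry_xyz(geom_path)
                traj = cio.read_hamiltonian(ham_path)
            except (ValueError, KeyError, IndexError) as exc:
                raise PipelineError(
                    "stage 'spectra': corrupt input file; re-run earlier stages"
                ) from exc
            origins = tuple(
                r * spec_cfg.realization_stride for r in range(spec_cfg.n_realizations)
            )
            omega, absorb = linear_response(
                traj,
                geometry,
                t_max=config.spectroscopy.linear_t_max,
                apod_tau=spec_cfg.apod_tau,
                origins=origins,
            )
            np.savetxt(
                out / "absorption.tsv",
                np.column_stack([omega, absorb]),
                delimiter="\t",
                header="omega_cm\tabsorption",
                comments="",
            )
            spectra = []
            for t2 in spec_cfg.t2_list:
                sp = twodes_spectrum(
                    traj, geometry, spec_cfg, t2, window=(12000.0, 19000.0)
                )
                cio.write_spectrum_tsv(sp, out / f"spectrum2d_t2_{int(t2):04d}.tsv")
                spectra.append(sp)
            if len(spectra) > 1:
                peak = np.unravel_index(
                    np.argmax(np.abs(spectra[0].amplitude)), spectra[0].amplitude.shape
                )
                tr = point_trace(
                    spectra,
                    float(spectra[0].omega1[peak[0]]),
                    float(spectra[0].omega3[peak[1]]),
                )
                cio.write_trace_tsv(tr, out / "trace_main_peak.tsv")
            record("spectra", outs, t0)
        else:
            log.info("stage spectra skipped (up to date)")

    if "analysis" in stages:
        require("analysis", geom_path, ham_path)
        outs = [out / "band_states.tsv", out / "band_summary.json"]
        if not stage_done("analysis", outs):
            t0 = time.time()
            try:
                geometry = cio.read_geometry_xyz(geom_path)
                traj = cio.read_hamiltonian(ham_path)
            except (ValueError, KeyError, IndexError) as exc:
                raise PipelineError(
                    "stage 'analysis': corrupt input file; re-run earlier stages"
                ) from exc
            n_frames = min(config.analysis.n_frames, traj.n_frames)
            frames = [traj.frame(k) for k in range(n_frames)]
            report = ana.band_report(
                geometry,
                frames,
                dos_bin_width=config.analysis.dos_bin_width,
                n_low=config.analysis.n_low,
            )
            report.states_table.to_csv(out / "band_states.tsv", sep="\t", index=False)
            report.dark_states.to_csv(out / "dark_states.tsv", sep="\t", index=False)
            summary = {
                "angle_mean_deg": report.angle_mean_deg,
                "coupling_peaks": [
                    {"center_cm": p.center, "height": p.height, "assignment": p.assignment}
                    for p in report.coupling_peaks
                ],
                "n_frames": report.n_frames,
            }
            (out / "band_summary.json").write_text(json.dumps(summary, indent=2))
            record("analysis", outs, t0)
        else:
            log.info("stage analysis skipped (up to date)")

    return manifest
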