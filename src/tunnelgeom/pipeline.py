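"""End-to-end cohort pipeline: generate -> landmark -> solve -> measure -> CSV.

CSV is the single exchange format between the geometry and statistics layers;
a cohort run writes one measurement row per subject and approach, joined with
the subject covariates (sex, age, height), and is byte-reproducible from
(config, seed).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .cross_section import APPROACHES, build_entry_tracks
from .errors import MeshIntegrityError, SidecarError, TunnelGeomError, ValidationError
from .measure import measure_tunnel
from .plateau import extract_medial_rim, fit_plane_M
from .solver import TunnelSpec, posterior_cortex_samples, solve_max_angle_tunnel
from .synthetic import (GroundTruthLandmarks, PopulationConfig, SubjectParams,
                        generate_subject, sample_cohort)

log = logging.getLogger("tunnelgeom")

__all__ = ["RunConfig", "run_cohort", "analyze_subject", "load_external_mesh", "export_subject"]


@dataclass
class RunConfig:
    """Configuration of a cohort run (YAML round-trippable)."""
    n_subjects: int = 30
    seed: int = 0
    population: dict = field(default_factory=dict)   # PopulationConfig overrides
    tunnel_radius: float = 5.0
    clearance_tol: float = 0.05
    slice_step: float = 1.0
    flatness_tol: float = 0.25
    bisection_tol: float = 0.01
    sample_density: float = 24.0
    exclusion_radius: float | None = None            # default: radius + 1
    # exit-aperture allowance: on the sloped retro-plateau facet the drill exit
    # is an oblique oval that may run far along the facet; the facet band above
    # the cortex corner within this horizontal radius of the exit is aperture
    aperture_horizontal_radius: float = 16.0
    track_top_frac: float = 0.22                     # fractions of bone length below the plateau
    track_bottom_frac: float = 0.88
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("tunnel_radius", "clearance_tol", "slice_step", "flatness_tol",
                     "bisection_tol", "sample_density"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 < self.track_top_frac < self.track_bottom_frac < 1.0):
            raise ValidationError("track fractions must satisfy 0 < top < bottom < 1")

    def population_config(self) -> PopulationConfig:
        return dataclasses.replace(PopulationConfig(), **self.population)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def analyze_subject(subject: SubjectParams, config: RunConfig | None = None,
                    mesh: trimesh.Trimesh | None = None,
                    landmarks: GroundTruthLandmarks | None = None):
    """Run the full geometric pipeline for one subject.

    Returns (records, tunnels, plane_M): one measurement record per approach.
    """
    config = config or RunConfig()
    if mesh is None or landmarks is None:
        mesh, landmarks = generate_subject(subject)
    zmin, zmax = mesh.bounds[0][2], mesh.bounds[1][2]
    length = zmax - zmin
    z_hi = zmax - config.track_top_frac * length
    z_lo = zmax - config.track_bottom_frac * length
    step = config.slice_step * subject.global_scale
    tracks = build_entry_tracks(mesh, (z_hi, z_lo), slice_step=step,
                                flatness_tol=config.flatness_tol)
    rim = extract_medial_rim(mesh)
    plane_M = fit_plane_M(rim)
    B = landmarks.pcl_attachment_center
    cutoff = landmarks.posterior_cortex_plane.get("z_corner") if landmarks else None
    if cutoff is not None:
        # keep the corner ring itself solidly inside the protected set
        cutoff = cutoff + 0.5 * subject.global_scale
    samples = posterior_cortex_samples(
        mesh, B, exclusion_radius=config.exclusion_radius,
        radius=config.tunnel_radius, plane_M=plane_M,
        density=config.sample_density,
        aperture_cutoff_z=cutoff,
        aperture_horizontal_radius=config.aperture_horizontal_radius,
        seed=subject.seed)
    records, tunnels = [], {}
    for a in APPROACHES:
        spec = TunnelSpec(exit_B=B, track=tracks[a], radius=config.tunnel_radius,
                          clearance_tol=config.clearance_tol)
        tun = solve_max_angle_tunnel(mesh, spec, plane_M, samples=samples,
                                     z_tol=config.bisection_tol, seed=subject.seed)
        tunnels[a] = tun
        records.append(measure_tunnel(subject.subject_id, tun, plane_M))
    return records, tunnels, plane_M


def run_cohort(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Generate a synthetic cohort and measure all five approaches per subject.

    Per-subject failures are logged and skipped; more than 50% failures abort
    the run.  Returns the cohort table (one row per subject x approach) and,
    when ``write`` is set, saves ``measurements.csv`` under ``out_dir``.
    """
    subjects = sample_cohort(config.n_subjects, config.seed, config.population_config())
    rows = []
    failures = []
    for subj in subjects:
        try:
            records, _, _ = analyze_subject(subj, config)
        except TunnelGeomError as exc:
            log.warning("subject %s failed: %s", subj.subject_id, exc)
            failures.append((subj.subject_id, str(exc)))
            continue
        for rec in records:
            rows.append({
                "subject_id": rec.subject_id, "approach": rec.approach,
                "psa_deg": rec.PSA, "tth_mm": rec.TTH, "ttd_mm": rec.TTD,
                "sex": subj.sex, "age": subj.age, "height_m": subj.height,
                "global_scale": subj.global_scale,
            })
    if len(failures) > 0.5 * len(subjects):
        raise TunnelGeomError(
            f"{len(failures)}/{len(subjects)} subjects failed; first: {failures[0]}")
    df = pd.DataFrame(rows)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "measurements.csv", index=False, float_format="%.6f")
        if failures:
            with open(out / "failures.json", "w") as fh:
                json.dump(failures, fh, indent=1)
    return df


# ---------------------------------------------------------------------------
# external mesh I/O
# ---------------------------------------------------------------------------

def export_subject(subject: SubjectParams, out_dir, fmt: str = "stl") -> tuple[Path, Path]:
    """Write one generated mesh plus its landmark sidecar; returns the paths."""
    mesh, lm = generate_subject(subject)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh_path = out / f"{subject.subject_id}.{fmt}"
    mesh.export(mesh_path)
    sidecar = out / f"{subject.subject_id}.landmarks.json"
    lm.save(sidecar)
    return mesh_path, sidecar


def load_external_mesh(path, landmark_sidecar) -> tuple[trimesh.Trimesh, dict]:
    """Load a user-supplied mesh (STL/PLY) with its landmark sidecar.

    The sidecar must provide at least ``pcl_attachment_center``; a
    ``side: left`` entry mirrors the mesh (and point landmarks) across the
    sagittal plane into the right-knee frame.  Non-watertight meshes get one
    repair attempt before failing.
    """
    mesh = trimesh.load(path, force="mesh")
    with open(landmark_sidecar) as fh:
        sidecar = json.load(fh)
    if "pcl_attachment_center" not in sidecar:
        raise SidecarError("landmark sidecar is missing key 'pcl_attachment_center'")
    if not mesh.is_watertight:
        # STL stores a triangle soup; restore shared vertices first
        mesh.merge_vertices()
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
        if not mesh.is_watertight:
            raise MeshIntegrityError(f"mesh {path} is not watertight after repair")
    if str(sidecar.get("side", "right")).lower() == "left":
        mirror = np.diag([-1.0, 1.0, 1.0, 1.0])
        mesh.apply_transform(mirror)
        mesh.invert()
        for key in ("pcl_attachment_center",):
            pt = np.asarray(sidecar[key], dtype=float)
            pt[0] = -pt[0]
            sidecar[key] = pt.tolist()
        if "plateau_rim_curve" in sidecar:
            rc = np.asarray(sidecar["plateau_rim_curve"], dtype=float)
            rc[:, 0] = -rc[:, 0]
            sidecar["plateau_rim_curve"] = rc.tolist()
        sidecar["side"] = "right"
    if mesh.volume < 0:
        mesh.invert()
    return mesh, sidecar
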