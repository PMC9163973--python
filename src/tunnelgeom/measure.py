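"""Tunnel measurements against plane M.

    PSA  angle between the tunnel centerline and plane M (degrees);
    TTH  distance from the entry point A to plane M (mm);
    TTD  length of the centerline segment A-B (mm).

PSA is computed in closed form as arcsin(|axis . normal|); the classical
witness construction - plane N through the centerline perpendicular to
plane M, S the centerline/plane intersection, P on the M-N intersection
line, PSA = angle ASP - is built alongside for parity and visual output and
agrees with the closed form to numerical precision.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import unit
from .errors import ValidationError
from .plateau import PlateauPlane
from .solver import Tunnel

__all__ = ["MeasurementRecord", "AngleWitness", "compute_psa", "compute_tth", "compute_ttd"]

CSV_HEADER = "subject_id,approach,psa_deg,tth_mm,ttd_mm"


@dataclass
class MeasurementRecord:
    subject_id: str
    approach: str
    PSA: float      # degrees
    TTH: float      # mm
    TTD: float      # mm

    def validate(self) -> None:
        if not (0.0 <= self.PSA <= 90.0):
            raise ValidationError(f"PSA out of [0, 90]: {self.PSA}")
        if self.TTH < 0 or self.TTD < 0:
            raise ValidationError("TTH/TTD must be non-negative")
        if not all(np.isfinite([self.PSA, self.TTH, self.TTD])):
            raise ValidationError("non-finite measurement")

    def to_csv_row(self) -> str:
        return f"{self.subject_id},{self.approach},{self.PSA:.6f},{self.TTH:.6f},{self.TTD:.6f}"


@dataclass
class AngleWitness:
    S: np.ndarray                 # centerline ∩ plane M
    P: np.ndarray                 # a point on plane M ∩ plane N
    plane_N_normal: np.ndarray
    degenerate: bool = False


def compute_psa(tunnel: Tunnel, plane_M: PlateauPlane) -> tuple[float, AngleWitness]:
    """Permissive safe angle of the tunnel, with the plane-N witness.

    Vertical tunnels (axis along the plane normal) return PSA = 90 with a
    degenerate witness flagged.
    """
    axis = np.asarray(tunnel.axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValidationError("zero-length tunnel axis")
    axis = axis / nrm
    n = unit(plane_M.normal)
    s = float(np.clip(abs(axis @ n), 0.0, 1.0))
    psa = float(np.degrees(np.arcsin(s)))

    denom = float(axis @ n)
    proj = axis - (axis @ n) * n          # axis projected into plane M
    if np.linalg.norm(proj) < 1e-12:
        witness = AngleWitness(S=np.asarray(tunnel.exit_B, dtype=float),
                               P=np.asarray(tunnel.exit_B, dtype=float),
                               plane_N_normal=np.zeros(3), degenerate=True)
        return psa, witness
    # S: intersection of the centerline with plane M
    A = np.asarray(tunnel.entry_A, dtype=float)
    if abs(denom) < 1e-12:
        S = A                              # axis parallel to the plane
    else:
        t = -float((A - plane_M.E) @ n) / denom
        S = A + t * axis
    n_N = unit(np.cross(axis, n))          # plane N contains axis and the normal direction
    line_dir = unit(np.cross(n, n_N))      # plane M ∩ plane N
    # orient P so that angle ASP measures the inclination of SA against the plane
    in_plane_SA = (A - S) - float((A - S) @ n) * n
    if np.linalg.norm(in_plane_SA) > 1e-12 and line_dir @ in_plane_SA < 0:
        line_dir = -line_dir
    P = S + 10.0 * line_dir
    witness = AngleWitness(S=S, P=P, plane_N_normal=n_N)
    return psa, witness


def witness_angle_deg(tunnel: Tunnel, witness: AngleWitness) -> float:
    """Angle ASP of the witness construction (degrees)."""
    if witness.degenerate:
        return 90.0
    u = np.asarray(tunnel.entry_A, dtype=float) - witness.S
    v = witness.P - witness.S
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_tth(entry_A: np.ndarray, plane_M: PlateauPlane) -> float:
    """Unsigned distance from the entry point to plane M."""
    return float(abs(plane_M.signed_distance(entry_A)[0]))


def compute_ttd(entry_A: np.ndarray, exit_B: np.ndarray) -> float:
    """Euclidean entry-to-exit length of the tunnel centerline."""
    return float(np.linalg.norm(np.asarray(exit_B, dtype=float)
                                - np.asarray(entry_A, dtype=float)))


def measure_tunnel(subject_id: str, tunnel: Tunnel, plane_M: PlateauPlane) -> MeasurementRecord:
    psa, _ = compute_psa(tunnel, plane_M)
    rec = MeasurementRecord(
        subject_id=subject_id, approach=tunnel.approach, PSA=psa,
        TTH=compute_tth(tunnel.entry_A, plane_M),
        TTD=compute_ttd(tunnel.entry_A, tunnel.exit_B),
    )
    rec.validate()
    return rec
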