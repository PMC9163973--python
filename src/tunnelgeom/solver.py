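"""Maximally inclined safe tunnel solver.

A tibial tunnel is a cylinder of given radius (default 5 mm) about the
segment joining an entry point A on the anterior cortex to the fixed exit
point B at the tibial PCL attachment.  Safety means the cylinder leaves the
posterior tibial cortex intact: the minimum clearance over a dense sample of
the posterior-facing cortex (below plane M, outside an exclusion sphere
around the exit aperture) must be non-negative.

Moving the entry distally along its track inclines the tunnel; the solver
returns the most distal - hence most inclined - feasible entry, located by a
coarse proximal-to-distal scan followed by bisection onto the feasibility
boundary, where the cylinder is tangent to the posterior cortex.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._geom import point_segment_distance
from .cross_section import EntryTrack
from .errors import InfeasibleTunnelError, TunnelGeomError, ValidationError
from .plateau import PlateauPlane

__all__ = ["TunnelSpec", "Tunnel", "posterior_cortex_samples", "clearance",
           "solve_max_angle_tunnel"]


@dataclass
class TunnelSpec:
    """Search specification for one approach."""
    exit_B: np.ndarray
    track: EntryTrack
    radius: float = 5.0
    search_z: tuple[float, float] | None = None   # defaults to the track extent
    clearance_tol: float = 0.05

    def __post_init__(self):
        self.exit_B = np.asarray(self.exit_B, dtype=float)
        if self.radius <= 0:
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if self.clearance_tol <= 0:
            raise ValidationError(f"clearance_tol must be > 0, got {self.clearance_tol}")
        lo, hi = self.track.z_extent
        if self.search_z is None:
            self.search_z = (lo, hi)
        else:
            a, b = min(self.search_z), max(self.search_z)
            if b <= lo or a >= hi:
                raise ValidationError("search_z does not overlap the track extent")
            self.search_z = (max(a, lo), min(b, hi))


@dataclass
class Tunnel:
    approach: str
    entry_A: np.ndarray
    exit_B: np.ndarray
    axis: np.ndarray          # unit, A -> B
    radius: float
    clearance: float
    converged: bool
    monotone_scan: bool = True
    scan_table: np.ndarray | None = field(default=None, repr=False)  # (n, 2): z, clearance


def posterior_cortex_samples(mesh: trimesh.Trimesh, exit_B: np.ndarray,
                             exclusion_radius: float | None = None,
                             radius: float = 5.0,
                             plane_M: PlateauPlane | None = None,
                             density: float = 4.0,
                             posterior=(0.0, -1.0, 0.0),
                             cone_deg: float = 60.0,
                             aperture_cutoff_z: float | None = None,
                             aperture_horizontal_radius: float | None = None,
                             seed: int = 0) -> np.ndarray:
    """Surface samples of the posterior cortex to be protected.

    Eligible faces have outward normals within ``cone_deg`` of the posterior
    direction and lie below plane M (when given).  The returned set is the
    union of area-weighted random samples at >= ``density`` points/mm^2 with
    the eligible faces' vertices and edge midpoints, so sharp cortical edges
    are represented exactly.  Points within ``exclusion_radius`` (default
    radius + 1 mm) of the exit are removed: they belong to the exit aperture.

    For anatomies where the exit sits on a sloped retro-plateau facet the
    drill aperture is an oblique oval that can run far along the facet; pass
    ``aperture_cutoff_z`` (the level where the straight posterior cortex
    resumes) and ``aperture_horizontal_radius`` to additionally exempt the
    facet band above that level near the exit - the protected cortex is then
    exactly the wall below the facet.
    """
    exit_B = np.asarray(exit_B, dtype=float)
    if exclusion_radius is None:
        exclusion_radius = radius + 1.0
    post = np.asarray(posterior, dtype=float)
    post = post / np.linalg.norm(post)
    cos_min = np.cos(np.radians(cone_deg))
    mask = mesh.face_normals @ post >= cos_min
    if plane_M is not None:
        centers_ok = plane_M.signed_distance(mesh.triangles_center) < 0
        mask &= centers_ok
    if not mask.any():
        raise TunnelGeomError("no posterior-facing cortex faces found")
    tri = mesh.vertices[mesh.faces[mask]]            # (m, 3, 3)
    areas = mesh.area_faces[mask]
    # deterministic per-face barycentric lattice, count proportional to area:
    # area-weighted at >= the requested density, independent of face order and
    # robust to mesh I/O round-trips (no RNG in the min-clearance statistic)
    k = np.maximum(1, np.ceil(density * areas).astype(int))
    res = np.ceil(np.sqrt(2.0 * k)).astype(int)
    lattice_pts = [np.empty((0, 3))]
    for n in np.unique(res):
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        keep_ij = ii + jj <= n - 1
        u = (ii[keep_ij] + 1.0 / 3.0) / n
        v = (jj[keep_ij] + 1.0 / 3.0) / n
        bary = np.column_stack([1.0 - u - v, u, v])          # (L, 3)
        sel = tri[res == n]                                  # (f, 3, 3)
        lattice_pts.append(np.einsum("lk,fkd->fld", bary, sel).reshape(-1, 3))
    verts = tri.reshape(-1, 3)
    mids = 0.5 * (tri + np.roll(tri, 1, axis=1)).reshape(-1, 3)
    pts = np.vstack(lattice_pts + [verts, mids])
    keep = np.linalg.norm(pts - exit_B, axis=1) > exclusion_radius
    if aperture_cutoff_z is not None and aperture_horizontal_radius is not None:
        horiz = np.linalg.norm(pts[:, :2] - exit_B[:2], axis=1)
        in_band = (pts[:, 2] > aperture_cutoff_z) & (horiz < aperture_horizontal_radius)
        keep &= ~in_band
    pts = pts[keep]
    if len(pts) == 0:
        warnings.warn("exclusion radius removed every posterior cortex sample",
                      RuntimeWarning, stacklevel=2)
    return pts


def clearance(entry_A: np.ndarray, spec: TunnelSpec, samples: np.ndarray) -> float:
    """Minimum signed clearance of the cylinder about segment A-B.

    ``min over samples of (distance to segment A-B) - radius``; negative
    values mean the cylinder breaches the cortex.
    """
    entry_A = np.asarray(entry_A, dtype=float)
    if np.allclose(entry_A, spec.exit_B):
        raise ValidationError("entry and exit coincide")
    samples = np.atleast_2d(samples)
    if samples.size == 0:
        raise ValidationError("empty posterior cortex sample set")
    d = point_segment_distance(samples, entry_A, spec.exit_B)
    return float(d.min() - spec.radius)


def solve_max_angle_tunnel(mesh: trimesh.Trimesh, spec: TunnelSpec,
                           plane_M: PlateauPlane,
                           samples: np.ndarray | None = None,
                           coarse_step: float = 2.0,
                           z_tol: float = 0.01,
                           seed: int = 0) -> Tunnel:
    """Most inclined safe tunnel for one approach.

    Scans the entry track from its proximal end (which must be feasible)
    distally in ``coarse_step`` increments; the first sign change brackets
    the feasibility boundary, refined by bisection to ``z_tol``.  If the
    coarse scan shows a non-monotone clearance profile the solver falls back
    to an exhaustive scan and flags the result.

    The search runs on the track's own arclength-like parameter (the height
    coordinate of the track polyline), so the solve is invariant under rigid
    motions applied consistently to mesh, track, exit and plane.
    """
    if samples is None:
        samples = posterior_cortex_samples(mesh, spec.exit_B, radius=spec.radius,
                                           plane_M=plane_M, seed=seed)
    z_lo, z_hi = spec.search_z

    track = spec.track

    def entry(z):
        return track.point_at_z(float(z))

    def clr(z):
        return clearance(entry(z), spec, samples)

    zs = np.arange(z_hi, z_lo - 1e-9, -coarse_step)
    if zs[-1] > z_lo + 1e-9:
        zs = np.append(zs, z_lo)
    cl = np.array([clr(z) for z in zs])
    scan_table = np.column_stack([zs, cl])
    if np.all(cl < 0):
        raise InfeasibleTunnelError(
            f"approach {track.approach}: no entry on the track clears the posterior "
            f"cortex (best clearance {cl.max():.3f} mm)")
    if cl[0] < 0:
        warnings.warn(
            f"approach {track.approach}: shallowest candidate entry breaches the "
            "posterior cortex; continuing from the feasible interior of the track",
            RuntimeWarning, stacklevel=2)

    neg = np.flatnonzero(cl < 0)
    monotone = True
    if len(neg) == 0:
        # whole track feasible: the most distal point is the answer
        z_star = float(zs[-1])
        A = entry(z_star)
        c_star = clr(z_star)
    else:
        first = int(neg[0])
        feas = np.flatnonzero(cl >= 0)
        if first == 0 or not np.all(cl[first:] < 0):
            # non-monotone clearance: take the most distal feasible point of the
            # full scan and bisect against its distal infeasible neighbour
            monotone = False
            first = int(feas[-1]) + 1
        if first >= len(zs):
            # most distal scan point is feasible; nothing to bisect against
            z_star = float(zs[-1])
            A = entry(z_star)
            c_star = clr(z_star)
            axis = spec.exit_B - A
            axis = axis / np.linalg.norm(axis)
            return Tunnel(approach=track.approach, entry_A=A, exit_B=spec.exit_B,
                          axis=axis, radius=spec.radius, clearance=float(c_star),
                          converged=False, monotone_scan=monotone, scan_table=scan_table)
        z_feas, z_inf = float(zs[first - 1]), float(zs[first])
        while z_feas - z_inf > z_tol:
            mid = 0.5 * (z_feas + z_inf)
            if clr(mid) >= 0:
                z_feas = mid
            else:
                z_inf = mid
        z_star = z_feas
        A = entry(z_star)
        c_star = clr(z_star)

    axis = spec.exit_B - A
    axis = axis / np.linalg.norm(axis)
    boundary = len(neg) > 0
    converged = bool(c_star >= 0 and (not boundary or c_star <= spec.clearance_tol))
    return Tunnel(approach=track.approach, entry_A=A, exit_B=spec.exit_B,
                  axis=axis, radius=spec.radius, clearance=float(c_star),
                  converged=converged, monotone_scan=monotone,
                  scan_table=scan_table)
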