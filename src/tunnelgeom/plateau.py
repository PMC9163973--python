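"""Medial tibial plateau reference plane (plane M).

The measurement reference of the whole pipeline is the plane of the medial
tibial plateau, built from three rim landmarks found via a best-fit circle on
the medial plateau rim:

    E  peak point of the anterior side of the medial plateau rim
    F  most medial point of the plateau rim
    G  peak point of the posterior side of the medial plateau rim

The rim is the boundary of the upward-facing plateau surface restricted to
the medial half; the circle halves it into anterior/posterior parts; E, F, G
are selected among the rim vertices (no interpolation) and plane M is the
plane through them with its normal oriented proximally.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import trimesh

from ._geom import fit_circle_2d, fit_plane_lsq, unit
from .errors import DegeneratePlaneError, TunnelGeomError

__all__ = ["PlateauPlane", "extract_medial_rim", "fit_plane_M"]


@dataclass
class PlateauPlane:
    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    normal: np.ndarray
    circle_center: np.ndarray
    circle_radius: float

    def __post_init__(self):
        for name in ("E", "F", "G", "normal", "circle_center"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.normal[2] <= 0:
            raise DegeneratePlaneError("plane M normal must point proximally (+z hemisphere)")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to plane M; positive on the proximal side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.E) @ self.normal

    def to_json_dict(self) -> dict:
        return {
            "E": self.E.tolist(), "F": self.F.tolist(), "G": self.G.tolist(),
            "normal": self.normal.tolist(),
            "center": self.circle_center.tolist(), "radius": self.circle_radius,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PlateauPlane":
        return cls(E=d["E"], F=d["F"], G=d["G"], normal=d["normal"],
                   circle_center=d["center"], circle_radius=d["radius"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def extract_medial_rim(mesh: trimesh.Trimesh, up=(0.0, 0.0, 1.0),
                       cone_deg: float = 45.0, medial_half: bool = True,
                       medial_axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Ordered polyline of the plateau rim (medial half by default).

    The rim is the boundary of the largest connected patch of upward-facing
    surface (face normal within ``cone_deg`` of ``up``); with ``medial_half``
    only the part of the boundary with positive coordinate along
    ``medial_axis`` is returned (right-knee frame: x > 0).
    """
    up = unit(np.asarray(up, dtype=float))
    cos_min = np.cos(np.radians(cone_deg))
    mask = mesh.face_normals @ up >= cos_min
    if not mask.any():
        raise TunnelGeomError("no upward-facing surface found for rim extraction")
    # largest connected component of the upward patch
    sub_faces = np.flatnonzero(mask)
    patch = mesh.submesh([sub_faces], append=True)
    comps = patch.split(only_watertight=False)
    if len(comps) > 1:
        patch = max(comps, key=lambda c: c.area)
    # boundary edges: referenced by exactly one face of the patch
    edges = patch.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        raise TunnelGeomError("upward-facing patch has no boundary (closed surface?)")
    # chain the boundary edges into ordered loops, keep the longest
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen: set[int] = set()
    loops = []
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxts = [v for v in adj[cur] if v != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == loop[0]:
                break
            if nxt in seen:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    loop = max(loops, key=len)
    rim = patch.vertices[np.asarray(loop)]
    if medial_half:
        axis = unit(np.asarray(medial_axis, dtype=float))
        keep = rim @ axis > 0
        if not keep.any():
            raise TunnelGeomError("no rim points on the medial half")
        # rotate the loop so the kept run is contiguous, then slice it out
        if keep.all():
            return rim
        first_out = int(np.argmin(keep))
        order = np.roll(np.arange(len(rim)), -first_out)
        rim, keep = rim[order], keep[order]
        rim = rim[keep]
    return rim


def fit_plane_M(rim: np.ndarray) -> PlateauPlane:
    """Plane M from the medial rim polyline via the best-fit-circle method.

    A total-least-squares plane orients the working frame; the rim is
    projected into it and a least-squares circle fitted; the circle halves
    the rim into anterior/posterior parts; E/G are the rim vertices of
    maximal elevation in each half, F the most medial rim vertex; plane M
    passes through E, F, G with a proximally oriented normal.
    """
    rim = np.asarray(rim, dtype=float)
    if len(rim) < 8:
        raise DegeneratePlaneError(f"rim needs >= 8 points, got {len(rim)}")
    centroid, n0 = fit_plane_lsq(rim)
    if n0[2] < 0:
        n0 = -n0
    # in-plane basis aligned with anatomical axes as far as possible
    ex = np.array([1.0, 0.0, 0.0])
    u = ex - (ex @ n0) * n0
    if np.linalg.norm(u) < 1e-9:
        u = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ n0) * n0
    u = unit(u)                      # ~medial
    v = np.cross(n0, u)              # ~anterior
    xy = np.column_stack([(rim - centroid) @ u, (rim - centroid) @ v])
    c2d, radius = fit_circle_2d(xy)
    center3d = centroid + c2d[0] * u + c2d[1] * v

    ant = xy[:, 1] > c2d[1]
    post = ~ant
    if not ant.any() or not post.any():
        raise DegeneratePlaneError("circle center does not split the rim into halves")
    z = rim[:, 2]
    ztol = 1e-9 * (np.ptp(z) + np.linalg.norm(np.ptp(rim, axis=0)))

    def peak(mask, prefer_anterior: bool):
        idx = np.flatnonzero(mask)
        cand = idx[z[idx] >= z[idx].max() - ztol]
        # flat rims leave the elevation peak ill-defined: break ties by taking
        # the anterior-most (E) / posterior-most (G) of the candidates
        key = xy[cand, 1] if prefer_anterior else -xy[cand, 1]
        return int(cand[np.argmax(key)])

    iE = peak(ant, prefer_anterior=True)
    iG = peak(post, prefer_anterior=False)
    iF = int(np.argmax(xy[:, 0]))
    E, F, G = rim[iE], rim[iF], rim[iG]

    normal = np.cross(F - E, G - E)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-9 * max(np.linalg.norm(F - E), 1.0):
        raise DegeneratePlaneError("E, F, G are collinear")
    normal = normal / nrm
    if normal[2] < 0:
        normal = -normal
    return PlateauPlane(E=E, F=F, G=G, normal=normal,
                        circle_center=center3d, circle_radius=float(radius))
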