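"""Axial cross-sections of the proximal tibia and the five tunnel entry tracks.

The proximal tibial shaft outline is segmented into two straight cortical
runs - the oblique anteromedial (AM) flat and the near-perpendicular
anterolateral (AL) flat - joined by the rounded tibial crest, with the
posterior cortex closing the outline.  Extending the two flats to the
posterior-cortex tangent line yields the classical right-triangle
construction of the proximal tibia; the five entry approaches are defined on
it:

    T1  anterior 1/3 of the AM flat        T4  anterior 1/3 of the AL flat
    T2  midpoint of the AM flat            T5  midpoint of the AL flat
    T3  midpoint of the tibial crest arc

"anterior 1/3" is measured from the crest-side (anterior) end of each flat.
Stacking per-slice entry points over an axial range yields one surface
polyline ("entry track") per approach; the tunnel solver searches along it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry
import trimesh

from ._geom import polyline_arclength, interp_polyline
from .errors import EmptySliceError, MeshIntegrityError, SegmentationError, ValidationError

APPROACHES = ("T1", "T2", "T3", "T4", "T5")


@dataclass
class CrossSectionOutline:
    """Closed planar outline of the bone at one axial level.

    ``polygon`` is an (n, 2) array of (x medial, y anterior) vertices,
    counter-clockwise viewed from proximal, not repeating the first vertex.
    """
    z_level: float
    polygon: np.ndarray

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if len(self.polygon) < 16:
            raise ValidationError(f"outline needs >= 16 vertices, got {len(self.polygon)}")


@dataclass
class CortexSegmentation:
    """AM/AL cortical flats, crest arc and posterior tangent of one outline."""
    am_flat: np.ndarray          # (2, 2), rows anterior endpoint then posterior
    al_flat: np.ndarray
    crest_arc: tuple[int, int]   # index range on the polygon (inclusive, may wrap)
    posterior_tangent: tuple[np.ndarray, np.ndarray]   # (point, unit direction)
    outline: CrossSectionOutline = field(repr=False)
    am_indices: tuple[int, int] = (0, 0)
    al_indices: tuple[int, int] = (0, 0)


@dataclass
class ApproachTriangle:
    """The extension-line triangle of the two flats and the posterior tangent."""
    vertex_am_post: np.ndarray
    vertex_al_post: np.ndarray
    vertex_apex: np.ndarray
    right_angle_at: str = "vertex_al_post"

    def angle_at_al_post_deg(self) -> float:
        u = self.vertex_apex - self.vertex_al_post
        v = self.vertex_am_post - self.vertex_al_post
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class EntryTrack:
    """Per-slice entry points of one approach, proximal to distal."""
    approach: str
    surface_polyline: np.ndarray   # (n, 3), z strictly decreasing

    def __post_init__(self):
        self.surface_polyline = np.asarray(self.surface_polyline, dtype=float)
        z = self.surface_polyline[:, 2]
        if not np.all(np.diff(z) < 0):
            raise ValidationError(f"track {self.approach}: z must strictly decrease")

    def point_at_z(self, z: float) -> np.ndarray:
        """Linear interpolation of the track at height z (clamped to extent)."""
        pts = self.surface_polyline
        zs = pts[:, 2][::-1]                     # increasing for interp
        z = float(np.clip(z, zs[0], zs[-1]))
        x = np.interp(z, zs, pts[:, 0][::-1])
        y = np.interp(z, zs, pts[:, 1][::-1])
        return np.array([x, y, z])

    @property
    def z_extent(self) -> tuple[float, float]:
        z = self.surface_polyline[:, 2]
        return float(z.min()), float(z.max())


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def slice_cross_section(mesh: trimesh.Trimesh, z_level: float,
                        plane_origin=None, plane_normal=None) -> CrossSectionOutline:
    """Largest closed intersection contour of the mesh with an axial plane.

    By default the plane is z = ``z_level``; an arbitrary plane may be given
    for diagnostic use (the 2D outline is then expressed in an in-plane basis
    completed from the normal).
    """
    if plane_origin is None:
        plane_origin = [0.0, 0.0, z_level]
    if plane_normal is None:
        plane_normal = [0.0, 0.0, 1.0]
    section = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if section is None:
        raise EmptySliceError(f"plane at z={z_level} does not intersect the mesh")
    loops3d = section.discrete
    if len(loops3d) == 0:
        raise EmptySliceError(f"plane at z={z_level} produced no contour")
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    # in-plane basis: for the axial default this is exactly (x, y)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    best = None
    for loop in loops3d:
        loop = np.asarray(loop)
        closed = np.allclose(loop[0], loop[-1], atol=1e-8)
        if not closed:
            raise MeshIntegrityError(f"open section contour at z={z_level}; mesh not watertight?")
        pts2d = np.column_stack([(loop[:-1] - plane_origin) @ u, (loop[:-1] - plane_origin) @ v])
        poly = shapely.geometry.Polygon(pts2d)
        if best is None or poly.area > best[1]:
            best = (pts2d, poly.area, poly)
    pts2d, _, poly = best
    if not poly.exterior.is_ccw:
        pts2d = pts2d[::-1]
    return CrossSectionOutline(z_level=z_level, polygon=pts2d)


# ---------------------------------------------------------------------------
# cortex segmentation
# ---------------------------------------------------------------------------

def _max_chord_deviation(pts: np.ndarray) -> float:
    """Largest perpendicular distance of interior points from the chord."""
    if len(pts) <= 2:
        return 0.0
    a, b = pts[0], pts[-1]
    ab = b - a
    nrm = np.linalg.norm(ab)
    if nrm == 0:
        return float(np.max(np.linalg.norm(pts - a, axis=1)))
    cross = np.abs((pts[1:-1] - a)[:, 0] * ab[1] - (pts[1:-1] - a)[:, 1] * ab[0]) / nrm
    return float(cross.max()) if len(cross) else 0.0


def _straight_runs(poly: np.ndarray, flatness_tol: float, min_length: float):
    """Maximal straight vertex runs (chord-deviation growth) on a closed polygon.

    Returns a list of (i_start, i_end, length) with indices modulo n; runs are
    maximal (not extendable) and mutually non-nested.
    """
    n = len(poly)
    runs = []
    for i in range(n):
        # grow j until the chord test fails; a single long edge is a valid run
        j = i + 2
        best_j = i + 1
        while j < i + n:
            pts = poly[np.arange(i, j + 1) % n]
            if _max_chord_deviation(pts) < flatness_tol:
                best_j = j
                j += 1
            else:
                break
        length = float(polyline_arclength(poly[np.arange(i, best_j + 1) % n])[-1])
        if length >= min_length:
            runs.append((i, best_j, length))
    # keep maximal, non-overlapping runs, longest first
    runs.sort(key=lambda r: -r[2])
    chosen: list[tuple[int, int, float]] = []
    covered = np.zeros(n, dtype=bool)
    for i, j, ln in runs:
        idx = np.arange(i, j + 1) % n
        if covered[idx].sum() > 0.4 * len(idx):
            continue
        covered[idx] = True
        chosen.append((i, j, ln))
    return chosen


def _trim_run(poly: np.ndarray, run, refine_tol: float = 0.05):
    """Trim run ends whose vertices stray from the run's least-squares line.

    Chord growth can absorb one or two vertices of an adjacent arc; trimming
    against a fitted line restores the true flat endpoints so entry points
    stay on the cortex.
    """
    n = len(poly)
    i, j, _ = run
    idx = np.arange(i, j + 1) % n
    for _ in range(3):
        pts = poly[idx]
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
        d = vt[0]
        res = np.abs((pts - c) @ np.array([d[1], -d[0]]))
        keep_lo = 0
        while keep_lo < len(idx) - 2 and res[keep_lo] > refine_tol:
            keep_lo += 1
        keep_hi = len(idx) - 1
        while keep_hi > keep_lo + 1 and res[keep_hi] > refine_tol:
            keep_hi -= 1
        if keep_lo == 0 and keep_hi == len(idx) - 1:
            break
        idx = idx[keep_lo:keep_hi + 1]
    length = float(polyline_arclength(poly[idx])[-1])
    span = (idx[-1] - idx[0]) % n
    return (int(idx[0]), int(idx[0] + span), length)


def segment_cortex(outline: CrossSectionOutline, flatness_tol: float = 0.25,
                   min_flat_length: float = 5.0) -> CortexSegmentation:
    """Identify the AM/AL cortical flats, the crest arc and the posterior tangent.

    The two longest anterior straight runs are the flats; the AL flat is the
    one more nearly perpendicular to the chord joining the two posterior flat
    ends, the posterior tangent is the support line of the posterior extreme
    perpendicular to the AL flat direction.
    """
    poly = outline.polygon
    n = len(poly)
    runs = _straight_runs(poly, flatness_tol, min_flat_length)
    runs = [_trim_run(poly, r) for r in runs]
    runs = [r for r in runs if r[2] >= min_flat_length]
    # outward normal of a CCW polygon edge direction d is (d_y, -d_x)
    anterior = []
    for i, j, ln in runs:
        idx = np.arange(i, j + 1) % n
        d = poly[idx[-1]] - poly[idx[0]]
        d = d / np.linalg.norm(d)
        nrm = np.array([d[1], -d[0]])
        if nrm[1] < -0.5:          # posterior-facing run: posterior cortex, not a flat
            continue
        anterior.append((i, j, ln, idx))
    if len(anterior) < 2:
        found = ", ".join(f"len={ln:.1f}mm" for _, _, ln, _ in anterior) or "none"
        raise SegmentationError(
            f"found fewer than two anterior straight runs >= {min_flat_length} mm "
            f"(flatness tol {flatness_tol} mm); anterior runs found: {found}")
    anterior.sort(key=lambda r: -r[2])
    r1, r2 = anterior[0], anterior[1]

    def endpoints(run):
        idx = run[3]
        return poly[idx[0]], poly[idx[-1]], idx

    # anterior endpoint of a run = the one closer to the apex; approximate the
    # apex as the point of the two runs farthest from both runs' outer ends.
    # Simpler and robust: the two runs meet near the crest; the anterior ends
    # are the pair of endpoints (one per run) that are closest to each other.
    a0, a1, idx_a = endpoints(r1)
    b0, b1, idx_b = endpoints(r2)
    pairs = [(np.linalg.norm(pa - pb), ia, ib)
             for ia, pa in ((0, a0), (1, a1)) for ib, pb in ((0, b0), (1, b1))]
    _, ia_ant, ib_ant = min(pairs)
    flat1 = np.array([a0, a1]) if ia_ant == 0 else np.array([a1, a0])   # [anterior, posterior]
    flat2 = np.array([b0, b1]) if ib_ant == 0 else np.array([b1, b0])
    idx1 = (int(idx_a[0]), int(idx_a[-1])) if ia_ant == 0 else (int(idx_a[-1]), int(idx_a[0]))
    idx2 = (int(idx_b[0]), int(idx_b[-1])) if ib_ant == 0 else (int(idx_b[-1]), int(idx_b[0]))

    post_chord = flat2[1] - flat1[1]
    if np.linalg.norm(post_chord) < 1e-9:
        raise SegmentationError("posterior flat endpoints coincide; cannot orient the triangle")
    post_chord /= np.linalg.norm(post_chord)

    def perp_score(flat):
        d = flat[0] - flat[1]
        d /= np.linalg.norm(d)
        return abs(float(np.dot(d, post_chord)))

    if perp_score(flat1) <= perp_score(flat2):
        al_flat, al_idx, am_flat, am_idx = flat1, idx1, flat2, idx2
    else:
        al_flat, al_idx, am_flat, am_idx = flat2, idx2, flat1, idx1

    # posterior tangent: support line perpendicular to the AL flat direction
    al_dir = al_flat[0] - al_flat[1]
    al_dir /= np.linalg.norm(al_dir)
    proj = poly @ al_dir
    support = poly[int(np.argmin(proj))]
    tangent_dir = np.array([al_dir[1], -al_dir[0]])

    # crest arc: the shorter polygon path between the two anterior flat ends
    # (the long way round is the posterior cortex)
    i_am, i_al = am_idx[0] % n, al_idx[0] % n
    fwd = np.arange(i_am, i_am + (i_al - i_am) % n + 1) % n
    bwd = np.arange(i_al, i_al + (i_am - i_al) % n + 1) % n
    len_fwd = float(polyline_arclength(poly[fwd])[-1]) if len(fwd) > 1 else 0.0
    len_bwd = float(polyline_arclength(poly[bwd])[-1]) if len(bwd) > 1 else 0.0
    crest_path = fwd if len_fwd <= len_bwd else bwd
    crest_arc = (int(crest_path[0]), int(crest_path[-1]))

    if np.linalg.norm(am_flat[0] - am_flat[1]) < min_flat_length or \
       np.linalg.norm(al_flat[0] - al_flat[1]) < min_flat_length:
        raise SegmentationError("identified flats shorter than the minimum length")

    return CortexSegmentation(
        am_flat=am_flat, al_flat=al_flat, crest_arc=crest_arc,
        posterior_tangent=(support, tangent_dir), outline=outline,
        am_indices=am_idx, al_indices=al_idx,
    )


def approach_triangle(seg: CortexSegmentation) -> ApproachTriangle:
    """Intersect the flat extension lines with each other and the tangent."""
    def line_intersect(p1, d1, p2, d2):
        A = np.column_stack([d1, -d2])
        if abs(np.linalg.det(A)) < 1e-12:
            raise SegmentationError("flat extension lines are parallel")
        t, _ = np.linalg.solve(A, p2 - p1)
        return p1 + t * d1

    d_am = seg.am_flat[0] - seg.am_flat[1]
    d_al = seg.al_flat[0] - seg.al_flat[1]
    p_t, d_t = seg.posterior_tangent
    apex = line_intersect(seg.am_flat[1], d_am, seg.al_flat[1], d_al)
    am_post = line_intersect(seg.am_flat[1], d_am, p_t, d_t)
    al_post = line_intersect(seg.al_flat[1], d_al, p_t, d_t)
    return ApproachTriangle(vertex_am_post=am_post, vertex_al_post=al_post, vertex_apex=apex)


# ---------------------------------------------------------------------------
# entry points and tracks
# ---------------------------------------------------------------------------

def locate_entry_points(seg: CortexSegmentation) -> dict[str, np.ndarray]:
    """The five entry points on one cross-section.

    T1/T4 lie at the anterior third of the AM/AL flats (from the crest-side
    end), T2/T5 at their midpoints, T3 at the arclength midpoint of the crest.
    """
    out = {}
    for key_third, key_mid, flat in (("T1", "T2", seg.am_flat), ("T4", "T5", seg.al_flat)):
        ant, post = flat
        if np.linalg.norm(post - ant) < 1e-9:
            raise SegmentationError("degenerate zero-length flat")
        out[key_third] = ant + (post - ant) / 3.0
        out[key_mid] = 0.5 * (ant + post)
    poly = seg.outline.polygon
    n = len(poly)
    i0, i1 = seg.crest_arc
    path = poly[np.arange(i0, i0 + (i1 - i0) % n + 1) % n]
    if len(path) == 1:
        out["T3"] = path[0]
    else:
        cum = polyline_arclength(path)
        out["T3"] = interp_polyline(path, cum[-1] / 2.0)
    return out


def build_entry_tracks(mesh: trimesh.Trimesh, z_range: tuple[float, float],
                       slice_step: float = 1.0, flatness_tol: float = 0.25,
                       min_flat_length: float = 5.0) -> dict[str, EntryTrack]:
    """Entry tracks for all five approaches over an axial range.

    Slices every ``slice_step`` mm from the proximal end of ``z_range`` down;
    circumferential identity across slices is kept by the fractional position
    along each flat, which is stable under taper.
    """
    if slice_step <= 0:
        raise ValidationError(f"slice_step must be > 0, got {slice_step}")
    z_hi, z_lo = max(z_range), min(z_range)
    z_levels = np.arange(z_hi, z_lo - 1e-9, -slice_step)
    points: dict[str, list[np.ndarray]] = {a: [] for a in APPROACHES}
    for z in z_levels:
        try:
            outline = slice_cross_section(mesh, float(z))
            seg = segment_cortex(outline, flatness_tol=flatness_tol,
                                 min_flat_length=min_flat_length)
            entries = locate_entry_points(seg)
        except (EmptySliceError, SegmentationError) as exc:
            raise SegmentationError(f"slice at z={z:.3f} failed: {exc}") from exc
        for a in APPROACHES:
            points[a].append(np.array([entries[a][0], entries[a][1], z]))
    return {a: EntryTrack(approach=a, surface_polyline=np.asarray(points[a]))
            for a in APPROACHES}
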