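"""Small geometry kernel shared by the pipeline stages.

Everything here is frame-free: points are (n, 3) or (3,) float arrays in
millimetres, directions are unit vectors.
"""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment a-b (vectorized)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def point_line_distance(points: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = unit(direction)
    rel = points - np.asarray(origin, dtype=float)
    proj = rel @ d
    return np.linalg.norm(rel - proj[:, None] * d, axis=1)


def fit_plane_lsq(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through a point cloud.

    Returns (centroid, unit normal); the normal is the singular vector of the
    smallest singular value of the centred cloud.
    """
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[-1]


def fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle fit (algebraic Kasa fit + one geometric Gauss-Newton step).

    Returns (center (2,), radius).
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(c + cx * cx + cy * cy))
    center = np.array([cx, cy])
    # one geometric refinement step on residuals r_i - r
    for _ in range(1):
        d = xy - center
        rho = np.linalg.norm(d, axis=1)
        ok = rho > 1e-12
        J = np.column_stack([-d[ok, 0] / rho[ok], -d[ok, 1] / rho[ok], -np.ones(ok.sum())])
        res = rho[ok] - r
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        center = center + step[:2]
        r = float(r + step[2])
    return center, r


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = unit(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation (QR of a Gaussian matrix) and a translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-100.0, 100.0, size=3)
    return q, t


def point_triangles_distance(point: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Distance from one point to each triangle (m, 3, 3), vectorized.

    Standard region-based closest-point-on-triangle (Ericson); used for
    surface-membership checks without a spatial index.
    """
    p = np.asarray(point, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    # barycentric interior solution
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    closest = a + v[:, None] * ab + w[:, None] * ac
    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, closest)
    # edge regions
    t_ab = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + np.clip(t_ab, 0, 1)[:, None] * ab, closest)
    t_ac = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + np.clip(t_ac, 0, 1)[:, None] * ac, closest)
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    t_bc = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[:, None], b + np.clip(t_bc, 0, 1)[:, None] * (c - b), closest)
    return np.linalg.norm(closest - p, axis=1)


def point_mesh_distance(point: np.ndarray, mesh) -> float:
    """Distance from a point to a trimesh surface (brute force over faces)."""
    return float(point_triangles_distance(point, mesh.triangles).min())


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength parameter of an (n, k) polyline, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def interp_polyline(points: np.ndarray, s: float | np.ndarray) -> np.ndarray:
    """Point(s) at arclength s along an (n, k) polyline (linear interpolation)."""
    points = np.asarray(points, dtype=float)
    cum = polyline_arclength(points)
    s = np.clip(np.asarray(s, dtype=float), 0.0, cum[-1])
    out = np.empty(np.shape(s) + (points.shape[1],))
    flat = np.atleast_1d(s)
    res = np.empty((flat.size, points.shape[1]))
    idx = np.clip(np.searchsorted(cum, flat, side="right") - 1, 0, len(cum) - 2)
    seg_len = cum[idx + 1] - cum[idx]
    frac = np.where(seg_len > 0, (flat - cum[idx]) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
    res = points[idx] + frac[:, None] * (points[idx + 1] - points[idx])
    out = res.reshape(np.shape(s) + (points.shape[1],))
    return out
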