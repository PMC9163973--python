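"""Parametric proximal-tibia generator.

Produces watertight triangle meshes of a proximal tibia in the anatomical
frame (+z proximal along the shaft axis, +y anterior, +x medial; right-knee
convention) together with analytic ground-truth landmarks, so that every
downstream stage (slicing, cortex segmentation, plateau-plane construction,
tunnel solving) can be tested against known geometry.

The axial cross-section follows the classic description of the proximal
tibial shaft: an oblique anteromedial cortical flat, an anterolateral flat
nearly perpendicular to the posterior margin, a rounded tibial crest joining
them, and a shallow posterior arc.  The profile is lofted along z with a mild
distal taper and a metaphyseal flare, capped proximally by a plateau plane
with a configurable posterior slope.  The PCL tibial attachment sits on a
vertical facet recessed anteriorly into the posterior cortex (the
retro-plateau / intercondylar fossa); the straight posterior cortex resumes
below the facet via a short shelf.  That recess is what gives a maximally
inclined tunnel a well-defined tangency against the posterior cortex.

All linear parameters are millimetres, angles degrees.  ``global_scale``
multiplies every vertex coordinate exactly, so meshes obey an exact isotropic
scaling law.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import trimesh

from .errors import ValidationError

__all__ = [
    "ShapeParams",
    "SubjectParams",
    "PopulationConfig",
    "GroundTruthLandmarks",
    "generate_subject",
    "sample_cohort",
    "analytic_section_area",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Shape of one proximal tibia (at unit global scale).

    ``ap_depth`` (crest tip to posterior cortex) is a *derived* quantity of
    the triangle construction; pass ``None`` (default) to let the generator
    compute it.  Supplying a value only records intent - the profile is
    always built from ``posterior_width`` and the two cortex angles.
    """

    shaft_length: float = 110.0
    posterior_width: float = 56.0
    am_cortex_angle: float = 50.0
    al_cortex_angle: float = 84.0
    crest_radius: float = 8.0
    ap_depth: float | None = None
    plateau_posterior_slope: float = 6.0
    attachment_depth: float = 4.5
    attachment_facet_height: float = 21.0
    # posterior geometry
    posterior_bulge: float = 3.0
    facet_tilt_deg: float = 10.0
    chamfer_halfwidth_full: float = 10.0
    chamfer_halfwidth_zero: float = 22.0
    attachment_x_offset: float = 5.0
    # loft shape
    metaphyseal_flare: float = 1.10
    distal_taper: float = 0.92
    flare_start: float = 18.0  # distance below plateau where the flare begins

    def validate(self) -> None:
        if not (0.0 < self.am_cortex_angle < self.al_cortex_angle <= 90.0):
            raise ValidationError(
                "require 0 < am_cortex_angle < al_cortex_angle <= 90, got "
                f"am={self.am_cortex_angle}, al={self.al_cortex_angle}"
            )
        if not (self.attachment_depth < self.attachment_facet_height < self.shaft_length):
            raise ValidationError(
                "require attachment_depth < attachment_facet_height < shaft_length, got "
                f"{self.attachment_depth}, {self.attachment_facet_height}, {self.shaft_length}"
            )
        for name in (
            "shaft_length", "posterior_width", "crest_radius", "attachment_depth",
            "attachment_facet_height", "posterior_bulge", "chamfer_halfwidth_full",
            "chamfer_halfwidth_zero", "flare_start",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.ap_depth is not None and self.ap_depth <= 0:
            raise ValidationError(f"ap_depth must be > 0, got {self.ap_depth}")
        if not (0.0 < self.facet_tilt_deg < 45.0):
            raise ValidationError("facet_tilt_deg must be in (0, 45)")
        if self.chamfer_halfwidth_full >= self.chamfer_halfwidth_zero:
            raise ValidationError("chamfer taper half-widths must increase")
        if not (0.0 < self.distal_taper <= 1.2) or self.metaphyseal_flare <= 0:
            raise ValidationError("taper/flare factors must be positive")


@dataclass(frozen=True)
class SubjectParams:
    """One synthetic subject: anthropometrics plus bone shape."""

    subject_id: str
    sex: Literal["male", "female"]
    age: float
    height: float  # metres
    global_scale: float
    shape: ShapeParams = field(default_factory=ShapeParams)
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0:
            raise ValidationError(f"height must be > 0, got {self.height}")
        if self.global_scale <= 0:
            raise ValidationError(f"global_scale must be > 0, got {self.global_scale}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.shape.validate()


@dataclass(frozen=True)
class PopulationConfig:
    """Distribution spec for :func:`sample_cohort`.

    Defaults emulate an adult surgical-imaging cohort: ~38% male, ages 16-60,
    sex-conditional heights, and an affine height-to-scale map
    ``scale = scale_intercept + scale_slope * height_m`` (default: bone size
    proportional to stature, unit scale at 1.66 m).
    """

    sex_ratio_male: float = 34.0 / 90.0
    age_range: tuple[float, float] = (16.0, 60.0)
    height_mean_male: float = 1.72
    height_mean_female: float = 1.60
    height_sd: float = 0.055
    height_bounds: tuple[float, float] = (1.40, 1.98)
    scale_intercept: float = 0.0
    scale_slope: float = 1.0 / 1.66
    # per-subject jitter (sd) of the main shape parameters
    sd_am_angle: float = 2.5
    sd_al_angle: float = 2.0
    sd_width: float = 3.0
    sd_crest_radius: float = 0.8
    sd_bulge: float = 0.4
    sd_slope: float = 1.5
    sd_attachment_depth: float = 0.12
    sd_facet_height: float = 0.25
    sd_facet_tilt: float = 0.8
    sd_x_offset: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.sex_ratio_male <= 1.0):
            raise ValidationError(f"sex_ratio_male must be in [0, 1], got {self.sex_ratio_male}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError(f"age_range must be increasing, got {self.age_range}")
        if self.height_sd <= 0 or self.height_bounds[0] >= self.height_bounds[1]:
            raise ValidationError("malformed height distribution")

    def height_to_scale(self, height_m: float) -> float:
        return self.scale_intercept + self.scale_slope * height_m


@dataclass
class GroundTruthLandmarks:
    """Generator-side truth used as oracles by the downstream stages."""

    pcl_attachment_center: np.ndarray            # (3,) tunnel exit point B
    plateau_rim_curve: np.ndarray                # (n, 3) ordered plateau rim polyline
    cortex_flat_params: dict                     # analytic AM/AL flat directions & angles
    posterior_cortex_plane: dict                 # straight posterior cortex description
    true_plane_M_normal: np.ndarray              # (3,) unit, +z hemisphere
    scale_profile: dict                          # z-knots / scale factors / base profile area

    def to_json_dict(self) -> dict:
        return {
            "pcl_attachment_center": self.pcl_attachment_center.tolist(),
            "plateau_rim_curve": self.plateau_rim_curve.tolist(),
            "cortex_flat_params": self.cortex_flat_params,
            "posterior_cortex_plane": self.posterior_cortex_plane,
            "true_plane_M_normal": self.true_plane_M_normal.tolist(),
            "scale_profile": self.scale_profile,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruthLandmarks":
        return cls(
            pcl_attachment_center=np.asarray(d["pcl_attachment_center"], dtype=float),
            plateau_rim_curve=np.asarray(d["plateau_rim_curve"], dtype=float),
            cortex_flat_params=d["cortex_flat_params"],
            posterior_cortex_plane=d["posterior_cortex_plane"],
            true_plane_M_normal=np.asarray(d["true_plane_M_normal"], dtype=float),
            scale_profile=d["scale_profile"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GroundTruthLandmarks":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# 2D profile skeleton
# ---------------------------------------------------------------------------

_N_FLAT_AM = 11
_N_CREST = 16
_N_FLAT_AL = 9
_N_POST_ARC = 10  # per side of the notch


class _ProfileSkeleton:
    """Analytic construction of the axial cross-section at unit scale.

    Vertex layout (counter-clockwise viewed from proximal, +z):
      [0 .. nA]                AM flat, posterior corner -> crest tangent
      (nA .. nA+nC)            crest arc
      [.. ]                    AL flat, crest tangent -> posterior corner
      [.. ]                    posterior arc (lateral part), notch wall/floor
                               vertices, posterior arc (medial part)
    The notch (retro-plateau pocket) vertices are always present; at notch
    depth 0 they collapse onto the posterior arc so every axial level shares
    one topology and the loft stays watertight.
    """

    def __init__(self, p: ShapeParams):
        self.p = p
        w = p.posterior_width
        a = np.radians(p.am_cortex_angle)
        b = np.radians(p.al_cortex_angle)
        self.P_am = np.array([w / 2.0, 0.0])
        self.P_al = np.array([-w / 2.0, 0.0])
        d_am = np.array([-np.cos(a), np.sin(a)])       # AM corner -> crest
        d_al = np.array([np.cos(b), np.sin(b)])        # AL corner -> crest
        # apex of the extension-line triangle
        A = np.column_stack([d_am, -d_al])
        t, s = np.linalg.solve(A, self.P_al - self.P_am)
        if t <= 0 or s <= 0:
            raise ValidationError("cortex angles do not form a triangle above the posterior tangent")
        self.apex = self.P_am + t * d_am
        # crest fillet tangent to both flats
        theta = np.pi - a - b                          # interior angle at the apex
        if theta <= 0:
            raise ValidationError("am_cortex_angle + al_cortex_angle must be < 180")
        tan_half = np.tan(theta / 2.0)
        toff = p.crest_radius / tan_half               # tangent offset from apex
        if toff >= min(t, s):
            raise ValidationError("crest_radius too large for the cortex triangle")
        self.T_am = self.apex - toff * d_am
        self.T_al = self.apex - toff * d_al
        bis = -(d_am + d_al)
        bis = bis / np.linalg.norm(bis)
        self.crest_center = self.apex + bis * (p.crest_radius / np.sin(theta / 2.0))
        self.d_am, self.d_al = d_am, d_al
        # posterior parabola through the two corners, sagitta posterior_bulge
        self.bulge = p.posterior_bulge
        self.half_w = w / 2.0
        # extra posterior vertex positions bracketing the attachment
        self.x_b = p.attachment_x_offset
        self.x_l = self.x_b - 4.0
        self.x_r = self.x_b + 4.0
        if not (-self.half_w * 0.9 < self.x_l < self.x_r < self.half_w * 0.9):
            raise ValidationError("attachment_x_offset too far lateral/medial for the posterior cortex")
        self._build_indices()

    # parabola: y(x) = -bulge * (1 - (x / half_w)^2)
    def y_arc(self, x):
        return -self.bulge * (1.0 - (np.asarray(x) / self.half_w) ** 2)

    def _build_indices(self) -> None:
        i = 0
        self.idx_am = (0, _N_FLAT_AM - 1)
        i += _N_FLAT_AM - 1                      # T_am shared with crest start
        self.idx_crest = (i, i + _N_CREST - 1)
        i += _N_CREST - 1
        self.idx_al = (i, i + _N_FLAT_AL - 1)
        i += _N_FLAT_AL - 1
        self.idx_post_start = i
        i += _N_POST_ARC                          # lateral arc, excludes x_l wall
        self.idx_notch = (i, i + 4)               # attachment-bracketing posterior vertices
        i += 5
        i += _N_POST_ARC - 1                      # medial arc back towards P_am (both ends excl.)
        self.n_vertices = i

    def base(self, scale: float) -> np.ndarray:
        """Profile polygon at an axial level (no pocket), isotropically scaled
        about the profile pivot; the five pocket placeholder vertices sit on
        the posterior arc so every level shares one topology."""
        lin = np.linspace(0.0, 1.0, _N_FLAT_AM)[:, None]
        am = self.P_am + lin * (self.T_am - self.P_am)
        # crest arc from T_am to T_al around crest_center
        v0 = self.T_am - self.crest_center
        v1 = self.T_al - self.crest_center
        a0 = np.arctan2(v0[1], v0[0])
        a1 = np.arctan2(v1[1], v1[0])
        while a1 <= a0:              # CCW outer arc
            a1 += 2 * np.pi
        ang = np.linspace(a0, a1, _N_CREST)
        crest = self.crest_center + self.p.crest_radius * np.column_stack([np.cos(ang), np.sin(ang)])
        al = self.T_al + np.linspace(0.0, 1.0, _N_FLAT_AL)[:, None] * (self.P_al - self.T_al)
        front = np.vstack([am[:-1], crest[:-1], al[:-1]])
        xs_lat = np.linspace(-self.half_w, self.x_l, _N_POST_ARC + 1)[:-1]
        lat = np.column_stack([xs_lat, self.y_arc(xs_lat)])
        xs_notch = np.array([self.x_l, 0.5 * (self.x_l + self.x_b), self.x_b,
                             0.5 * (self.x_b + self.x_r), self.x_r])
        notch = np.column_stack([xs_notch, self.y_arc(xs_notch)])
        xs_med = np.linspace(self.x_r, self.half_w, _N_POST_ARC + 1)[1:-1]
        med = np.column_stack([xs_med, self.y_arc(xs_med)])
        # the polygon closes from the last arc point straight back to P_am
        raw = np.vstack([front, lat, notch, med])[: self.n_vertices]
        c = self._centroid()
        return c + scale * (raw - c)

    def morph_round(self, ring: np.ndarray, weight: float) -> np.ndarray:
        """Condylar rounding: blend polar radii toward a circularly smoothed
        version; the plateau outline is far rounder than the shaft triangle."""
        if weight <= 0:
            return ring
        c = self._centroid()
        rel = ring - c
        r = np.linalg.norm(rel, axis=1)
        n = len(r)
        win = (max(5, int(0.18 * n))) | 1
        kernel = np.ones(win) / win
        pad = np.concatenate([r[-(win // 2):], r, r[: win // 2]])
        r_smooth = np.convolve(pad, kernel, mode="valid")
        r_new = (1.0 - weight) * r + weight * r_smooth
        return c + rel * (r_new / r)[:, None]

    def carve_chamfer(self, ring: np.ndarray, depth: float) -> np.ndarray:
        """Recess the posterior boundary anteriorly by ``depth`` (the
        champagne-glass drop-off below the overhanging posterior rim), with a
        cosine taper so the condylar bulges flanking the attachment keep
        their posterior extent."""
        if depth <= 0:
            return ring
        out = ring.copy()
        post_idx = np.arange(self.idx_post_start, self.n_vertices)
        x = out[post_idx, 0]
        dx = np.abs(x - self.x_b)
        w0, w1 = self.p.chamfer_halfwidth_full, self.p.chamfer_halfwidth_zero
        w = np.where(dx <= w0, 1.0,
                     np.where(dx >= w1, 0.0,
                              0.5 * (1.0 + np.cos(np.pi * (dx - w0) / (w1 - w0)))))
        out[post_idx, 1] += depth * w
        return out

    def vertices(self, scale: float, chamfer_depth: float, round_weight: float = 0.0) -> np.ndarray:
        return self.carve_chamfer(self.morph_round(self.base(scale), round_weight), chamfer_depth)

    def _centroid(self) -> np.ndarray:
        # centroid of the base outline vertices (stable, analytic enough for
        # a scaling pivot; does not need to be the area centroid)
        return np.array([0.0, 0.35 * self.apex[1]])

    def base_area(self) -> float:
        """Shoelace area of the unit-scale profile without the notch."""
        v = self.vertices(1.0, 0.0)
        x, y = v[:, 0], v[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


# ---------------------------------------------------------------------------
# loft
# ---------------------------------------------------------------------------

def _scale_of_z(z, p: ShapeParams):
    """Piecewise-linear loft scale: metaphyseal flare above ``-flare_start``,
    linear distal taper below, unit scale at the flare break."""
    z = np.asarray(z, dtype=float)
    zb = -p.flare_start
    flare = 1.0 + (p.metaphyseal_flare - 1.0) * np.clip((z - zb) / p.flare_start, 0.0, None)
    span = p.shaft_length - p.flare_start
    taper = 1.0 + (p.distal_taper - 1.0) * np.clip((zb - z) / span, 0.0, None)
    return np.where(z >= zb, flare, taper)


def _chamfer_depth_of_z(z, z_rim: float, p: ShapeParams):
    """Posterior chamfer depth: zero at the posterior rim, growing at
    tan(facet_tilt) per mm of descent until the straight cortex resumes at
    the corner (facet height below the rim), constant below."""
    drop = np.clip(z_rim - np.asarray(z, dtype=float), 0.0, p.attachment_facet_height)
    return np.tan(np.radians(p.facet_tilt_deg)) * drop


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _interp_ring_track(rings: np.ndarray, i_vertex: int, z: float) -> np.ndarray:
    """Point at height z on the vertex track ``i_vertex`` of the ring stack."""
    track_z = rings[:, i_vertex, 2]
    k = int(np.searchsorted(track_z[:-1], z, side="right") - 1)
    k = max(0, min(k, len(rings) - 2))
    f = (z - track_z[k]) / (track_z[k + 1] - track_z[k])
    return rings[k, i_vertex] + f * (rings[k + 1, i_vertex] - rings[k, i_vertex])


def generate_subject(params: SubjectParams) -> tuple[trimesh.Trimesh, GroundTruthLandmarks]:
    """Build the watertight mesh and ground-truth landmarks for one subject.

    Deterministic: identical ``(shape, seed)`` give byte-identical vertex
    buffers; ``global_scale`` multiplies every coordinate exactly.
    """
    params.validate()
    p = params.shape
    skel = _ProfileSkeleton(p)

    tan_slope = np.tan(np.radians(p.plateau_posterior_slope))
    flare = p.metaphyseal_flare
    round_max = 0.65          # condylar rounding weight at the plateau

    def round_weight(z):
        # same ramp as the metaphyseal flare: 0 below the flare break, full at the cap
        return round_max * float(np.clip((np.asarray(z) + p.flare_start) / p.flare_start, 0.0, 1.0))

    # posterior rim z near the pocket: cap plane z = tan_slope * y, with y taken
    # from the rounded cap outline at the pocket center
    cap_outline = skel.morph_round(skel.base(flare), round_max)
    post_idx = np.arange(skel.idx_post_start, skel.n_vertices)
    xs, ys = cap_outline[post_idx, 0], cap_outline[post_idx, 1]
    order = np.argsort(xs)
    y_rim_post = float(np.interp(skel.x_b, xs[order], ys[order]))
    z_rim_post = tan_slope * y_rim_post
    z_corner = z_rim_post - p.attachment_facet_height

    # axial levels: planar rings + the sloped cap ring
    z_cap_min = tan_slope * float(ys.min())
    z_joint = z_cap_min - 0.5
    shaft_levels = np.linspace(-p.shaft_length, -p.flare_start, 14)
    upper = np.linspace(-p.flare_start, z_joint, 10)
    breaks = np.array([z_corner, z_rim_post - p.attachment_depth])
    z_levels = np.unique(np.concatenate([shaft_levels, upper, breaks]))
    z_levels = z_levels[z_levels <= z_joint + 1e-12]
    if z_levels[-1] < z_joint:
        z_levels = np.append(z_levels, z_joint)

    n_prof = skel.n_vertices
    rings = []
    for z in z_levels:
        prof = skel.vertices(float(_scale_of_z(z, p)),
                             float(_chamfer_depth_of_z(z, z_rim_post, p)),
                             round_weight(z))
        rings.append(np.column_stack([prof, np.full(n_prof, z)]))
    # sloped cap ring: same profile as the joint ring, z from the cap plane
    cap_prof = skel.vertices(flare, 0.0, round_max)
    cap_z = tan_slope * cap_prof[:, 1]
    cap_ring = np.column_stack([cap_prof, cap_z])
    rings.append(cap_ring)
    rings = np.asarray(rings)
    n_rings = len(rings)

    verts = rings.reshape(-1, 3)
    faces = []
    for k in range(n_rings - 1):
        o0, o1 = k * n_prof, (k + 1) * n_prof
        for i in range(n_prof):
            j = (i + 1) % n_prof
            faces.append([o0 + i, o0 + j, o1 + j])
            faces.append([o0 + i, o1 + j, o1 + i])
    # bottom cap (fan, outward -z)
    c_bot = len(verts)
    bot = rings[0]
    verts = np.vstack([verts, bot.mean(axis=0)])
    for i in range(n_prof):
        j = (i + 1) % n_prof
        faces.append([c_bot, (i + 1) % n_prof, i])
    # top cap (fan on the cap plane, outward +z)
    c_top = len(verts)
    cap_centroid_xy = cap_prof.mean(axis=0)
    verts = np.vstack([verts, [cap_centroid_xy[0], cap_centroid_xy[1],
                               tan_slope * cap_centroid_xy[1]]])
    o_top = (n_rings - 1) * n_prof
    for i in range(n_prof):
        j = (i + 1) % n_prof
        faces.append([c_top, o_top + i, o_top + j])

    verts = verts * params.global_scale
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64),
                           process=False)
    if mesh.volume < 0:
        mesh.invert()

    # --- ground truth -----------------------------------------------------
    z_b = z_rim_post - p.attachment_depth
    # B lies on the facet-center vertex track: interpolate between rings
    i_floor = skel.idx_notch[0] + 2
    B = _interp_ring_track(rings, i_floor, z_b) * params.global_scale

    rim_curve = cap_ring * params.global_scale
    s = params.global_scale
    n_M = np.array([0.0, -tan_slope, 1.0])
    n_M = n_M / np.linalg.norm(n_M)
    lm = GroundTruthLandmarks(
        pcl_attachment_center=B,
        plateau_rim_curve=rim_curve,
        cortex_flat_params={
            "am_dir": skel.d_am.tolist(),
            "al_dir": skel.d_al.tolist(),
            "am_angle_deg": p.am_cortex_angle,
            "al_angle_deg": p.al_cortex_angle,
            "posterior_tangent_dir": [1.0, 0.0],
            "am_anchor": (skel.P_am * s).tolist(),
            "al_anchor": (skel.P_al * s).tolist(),
        },
        posterior_cortex_plane={
            "corner_point": (_interp_ring_track(rings, i_floor, z_corner) * s).tolist(),
            "normal": [0.0, -1.0, 0.0],
            "z_corner": float(z_corner) * s,
            "z_rim_post": float(z_rim_post) * s,
            "facet_tilt_deg": p.facet_tilt_deg,
            "bulge": p.posterior_bulge * s,
            "half_width": skel.half_w * s,
            "facet_gap": (p.attachment_facet_height - p.attachment_depth) * s,
        },
        true_plane_M_normal=n_M,
        scale_profile={
            "z_knots": (z_levels * s).tolist(),
            "scales": _scale_of_z(z_levels, p).tolist(),
            "areas": [float(_shoelace(r[:, :2])) * s * s for r in rings[:-1]],
            "global_scale": s,
        },
    )
    return mesh, lm


def analytic_section_area(landmarks: GroundTruthLandmarks, z: float) -> float:
    """Closed-form cross-section area at an axial level, from the generator's
    own ring profiles (independent of the mesh slicing machinery)."""
    sp = landmarks.scale_profile
    zk = np.asarray(sp["z_knots"])
    return float(np.interp(z, zk, np.asarray(sp["areas"])))


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(n: int, seed: int, population_config: PopulationConfig | None = None
                  ) -> list[SubjectParams]:
    """Draw ``n`` subjects with sex-conditional heights and jittered bone shape.

    Reproducible for a fixed seed; each subject also receives its own derived
    seed so downstream per-subject randomness stays independent.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    cfg = population_config or PopulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    base = ShapeParams()
    subjects = []
    for i in range(n):
        male = rng.random() < cfg.sex_ratio_male
        mean_h = cfg.height_mean_male if male else cfg.height_mean_female
        h = float(np.clip(rng.normal(mean_h, cfg.height_sd), *cfg.height_bounds))
        age = float(rng.uniform(*cfg.age_range))
        scale = cfg.height_to_scale(h)
        am = float(np.clip(rng.normal(base.am_cortex_angle, cfg.sd_am_angle), 43.0, 57.0))
        al = float(np.clip(rng.normal(base.al_cortex_angle, cfg.sd_al_angle), am + 20.0, 90.0))
        shape = dataclasses.replace(
            base,
            am_cortex_angle=am,
            al_cortex_angle=al,
            posterior_width=float(np.clip(rng.normal(base.posterior_width, cfg.sd_width), 49.0, 64.0)),
            crest_radius=float(np.clip(rng.normal(base.crest_radius, cfg.sd_crest_radius), 5.0, 12.0)),
            posterior_bulge=float(np.clip(rng.normal(base.posterior_bulge, cfg.sd_bulge), 1.5, 5.0)),
            plateau_posterior_slope=float(np.clip(rng.normal(base.plateau_posterior_slope, cfg.sd_slope), 2.0, 11.0)),
            # attachment geometry is ~size-invariant across statures: divide by
            # the global scale so the scaled facet gap stays constant in mm
            attachment_depth=float(np.clip(rng.normal(base.attachment_depth, cfg.sd_attachment_depth), 4.1, 4.9)) / scale,
            attachment_facet_height=float(np.clip(rng.normal(base.attachment_facet_height, cfg.sd_facet_height), 20.3, 21.7)) / scale,
            facet_tilt_deg=float(np.clip(rng.normal(base.facet_tilt_deg, cfg.sd_facet_tilt), 8.0, 12.0)),
            attachment_x_offset=float(np.clip(rng.normal(base.attachment_x_offset, cfg.sd_x_offset), 2.5, 7.5)),
        )
        subjects.append(SubjectParams(
            subject_id=f"S{i:03d}",
            sex="male" if male else "female",
            age=age,
            height=h,
            global_scale=scale,
            shape=shape,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return subjects
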