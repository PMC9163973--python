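"""Shared fixtures: a default synthetic subject, its solved pipeline, and the
planar-posterior-cortex slab used as a closed-form tangency oracle."""
import numpy as np
import pytest
import trimesh

from tunnelgeom.cross_section import EntryTrack
from tunnelgeom.pipeline import RunConfig, analyze_subject
from tunnelgeom.plateau import PlateauPlane
from tunnelgeom.synthetic import SubjectParams, generate_subject


@pytest.fixture(scope="session")
def default_subject() -> SubjectParams:
    return SubjectParams(subject_id="S000", sex="male", age=30.0, height=1.70,
                         global_scale=1.0, seed=7)


@pytest.fixture(scope="session")
def default_mesh(default_subject):
    return generate_subject(default_subject)


@pytest.fixture(scope="session")
def solved_default(default_subject, default_mesh):
    mesh, lm = default_mesh
    records, tunnels, plane_M = analyze_subject(default_subject, RunConfig(),
                                                mesh=mesh, landmarks=lm)
    return {"records": records, "tunnels": tunnels, "plane_M": plane_M,
            "mesh": mesh, "landmarks": lm}


def make_slab(m: float, depth_z: float = 180.0):
    """Box whose posterior face is the plane y = 0 for z in [-depth_z, -m].

    The exit B = (0, 0, 0) sits on that plane, m above the start of the
    cortex; the closed-form maximum safe angle for a radius-r cylinder is
    arccos(r / m).
    """
    box = trimesh.creation.box(extents=(90.0, 40.0, depth_z - m))
    box.apply_translation([0.0, 20.0, -(m + depth_z) / 2.0])
    return box


def slab_track(z_top: float = -5.0, z_bottom: float = -170.0, y: float = 40.0):
    zs = np.arange(z_top, z_bottom - 1e-9, -5.0)
    pts = np.column_stack([np.zeros_like(zs), np.full_like(zs, y), zs])
    return EntryTrack(approach="T3", surface_polyline=pts)


def horizontal_plane_M() -> PlateauPlane:
    return PlateauPlane(E=np.array([20.0, 5.0, 0.0]), F=np.array([0.0, -20.0, 0.0]),
                        G=np.array([-20.0, 5.0, 0.0]), normal=np.array([0.0, 0.0, 1.0]),
                        circle_center=np.zeros(3), circle_radius=20.0)


@pytest.fixture
def slab_factory():
    return make_slab


@pytest.fixture
def slab_track_factory():
    return slab_track


@pytest.fixture
def flat_plane_M():
    return horizontal_plane_M()
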