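"""Exception hierarchy for the tunnel-geometry pipeline."""


class TunnelGeomError(Exception):
    """Base class for all package errors."""


class ValidationError(TunnelGeomError, ValueError):
    """A parameter object violates one of its documented invariants."""


class EmptySliceError(TunnelGeomError):
    """A slicing plane does not intersect the mesh."""


class MeshIntegrityError(TunnelGeomError):
    """The mesh is not watertight / a section contour is open."""


class SegmentationError(TunnelGeomError):
    """Cortex segmentation could not find the required straight runs."""


class DegeneratePlaneError(TunnelGeomError):
    """Plateau landmarks are collinear; no plane can be constructed."""


class InfeasibleTunnelError(TunnelGeomError):
    """No entry point on the track yields a tunnel clearing the posterior cortex."""


class SidecarError(TunnelGeomError, KeyError):
    """A landmark sidecar file is missing a required key."""
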