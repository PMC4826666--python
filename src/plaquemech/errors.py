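"""Package-wide exception types."""


class PlaqueMechError(Exception):
    """Base class for all package errors."""


class InfeasibleGeometryError(PlaqueMechError, ValueError):
    """Requested geometric parameters would produce intersecting or
    non-nested contours."""


class GeometryFileError(PlaqueMechError, ValueError):
    """Malformed geometry file (open contour, self-intersection, broken
    containment chain, missing field)."""


class MeshingError(PlaqueMechError, ValueError):
    """Triangulation failed (degenerate contours or inverted elements)."""


class ConvergenceError(PlaqueMechError, RuntimeError):
    """Newton-Raphson failed to converge after the maximum number of load
    bisections; reduce the step or refine the mesh."""


class TrackingError(PlaqueMechError, ValueError):
    """Displacement estimation cannot proceed (flat signal, frame mismatch,
    insufficient overlap)."""
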