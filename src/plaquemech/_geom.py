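"""Small polygon helpers shared by the phantom, mesh and inverse modules.

Contours are closed polylines stored as (N, 2) float arrays in mm without a
repeated end vertex, oriented counter-clockwise in the (x, y) plane.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


def shoelace_area(contour: np.ndarray) -> float:
    """Signed polygon area by the shoelace formula (positive for CCW)."""
    x, y = np.asarray(contour, float).T
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def is_ccw(contour: np.ndarray) -> bool:
    return shoelace_area(contour) > 0.0


def ensure_ccw(contour: np.ndarray) -> np.ndarray:
    """Return the contour with counter-clockwise orientation."""
    contour = np.asarray(contour, float)
    return contour if is_ccw(contour) else contour[::-1].copy()


def to_polygon(contour: np.ndarray) -> Polygon:
    return Polygon(np.asarray(contour, float))


def is_simple(contour: np.ndarray) -> bool:
    """True if the closed polyline does not self-intersect."""
    return to_polygon(contour).is_valid


def strictly_contains(outer: np.ndarray, inner: np.ndarray, tol: float = 1e-9) -> bool:
    """True if polygon ``inner`` lies strictly inside polygon ``outer``."""
    po, pi = to_polygon(outer), to_polygon(inner)
    return po.buffer(-tol).contains(pi)


def resample_closed(contour: np.ndarray, n: int, start_index: int = 0) -> np.ndarray:
    """Resample a closed polyline to ``n`` points equally spaced in arc
    length, starting at vertex ``start_index``."""
    c = np.asarray(contour, float)
    c = np.roll(c, -start_index, axis=0)
    closed = np.vstack([c, c[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def radius_profile(contour: np.ndarray, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Radial distance from ``center`` to a star-shaped contour at ``angles``.

    The contour must be star-shaped about ``center``; the radius is obtained
    by periodic linear interpolation of vertex (angle, radius) pairs.
    """
    c = np.asarray(contour, float) - np.asarray(center, float)
    th = np.arctan2(c[:, 1], c[:, 0])
    r = np.hypot(c[:, 0], c[:, 1])
    order = np.argsort(th)
    th, r = th[order], r[order]
    th_ext = np.concatenate([th - 2 * np.pi, th, th + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    q = np.mod(np.asarray(angles, float) + np.pi, 2 * np.pi) - np.pi
    return np.interp(q, th_ext, r_ext)


def ellipse_polygon(center, semi_u, semi_v, u_dir, n: int = 48) -> np.ndarray:
    """CCW polygon approximating an ellipse.

    ``u_dir`` is the unit direction of the ``semi_u`` axis; the ``semi_v``
    axis is perpendicular to it.
    """
    u = np.asarray(u_dir, float)
    u = u / np.linalg.norm(u)
    v = np.array([-u[1], u[0]])
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = (np.asarray(center, float)[None, :]
           + np.outer(semi_u * np.cos(t), u)
           + np.outer(semi_v * np.sin(t), v))
    return ensure_ccw(pts)
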