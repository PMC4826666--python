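"""Histology-to-ultrasound contour registration.

Component contours drawn on a histology section are mapped onto the
ultrasound frame using only the two contours an operator can draw reliably
on both modalities: the lumen and the outer vessel wall.  Corresponding
landmarks are placed by matched arc-length parameterization of each contour
pair, rotationally anchored at the point of maximum wall thickness (an
anatomy-driven, reproducible anchor), and a 2D thin-plate-spline map is
fitted to the landmark pairs.  With zero regularization the TPS reproduces
any affine map exactly and interpolates the landmarks; a small bending-
energy weight absorbs histology shrinkage and tearing noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.interpolate import RBFInterpolator
from shapely.geometry import MultiPoint

from plaquemech import _geom

__all__ = ["ContourTransform", "fit_contour_transform", "apply_transform"]


@dataclass
class ContourTransform:
    """Thin-plate-spline point map fitted to contour landmark pairs."""

    source_points: np.ndarray
    target_points: np.ndarray
    regularization: float
    _rbf: RBFInterpolator

    @property
    def max_landmark_residual(self) -> float:
        """Largest distance between a mapped source landmark and its
        target (mm)."""
        mapped = self(self.source_points)
        return float(np.linalg.norm(mapped - self.target_points, axis=1).max())

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 2)
        hull = MultiPoint(self.source_points).convex_hull.buffer(
            0.1 * np.sqrt(MultiPoint(self.source_points).convex_hull.area + 1e-12))
        from shapely import contains_xy
        if not np.all(contains_xy(hull, pts[:, 0], pts[:, 1])):
            warnings.warn("some points lie far outside the landmark hull; "
                          "thin-plate-spline extrapolation is unreliable",
                          RuntimeWarning, stacklevel=2)
        return self._rbf(pts)


def _anchor_index(lumen: np.ndarray, outer: np.ndarray, n_probe: int = 720) -> float:
    """Angle (rad) of maximum wall thickness about the lumen centroid."""
    c = _geom.to_polygon(lumen).centroid
    center = np.array([c.x, c.y])
    ang = np.linspace(0, 2 * np.pi, n_probe, endpoint=False)
    r_l = _geom.radius_profile(lumen, center, ang)
    r_o = _geom.radius_profile(outer, center, ang)
    return float(ang[np.argmax(r_o - r_l)])


def _landmarks(contour: np.ndarray, anchor_angle: float, center: np.ndarray,
               n: int) -> np.ndarray:
    """n landmarks equally spaced in arc length, starting at the vertex
    closest in angle to the anchor, traversed CCW."""
    c = _geom.ensure_ccw(contour)
    rel = c - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    dist = np.abs(np.mod(ang - anchor_angle + np.pi, 2 * np.pi) - np.pi)
    start = int(np.argmin(dist))
    return _geom.resample_closed(c, n, start_index=start)


def fit_contour_transform(hist_lumen: np.ndarray, hist_outer: np.ndarray,
                          us_lumen: np.ndarray, us_outer: np.ndarray,
                          n_landmarks: int = 32,
                          regularization: float = 0.0) -> ContourTransform:
    """Fit the histology -> ultrasound thin-plate-spline transform.

    ``n_landmarks`` (>= 8) landmarks per contour are paired by matched
    arc-length parameterization anchored at the maximum-wall-thickness
    point of each image.  ``regularization`` is the TPS smoothing weight
    (0 = exact interpolation).
    """
    if n_landmarks < 8:
        raise ValueError("need at least 8 landmarks per contour")
    for name, cont in (("histology lumen", hist_lumen), ("histology outer", hist_outer),
                       ("ultrasound lumen", us_lumen), ("ultrasound outer", us_outer)):
        if not _geom.is_simple(np.asarray(cont, float)):
            raise ValueError(f"{name} contour is degenerate or self-intersecting")
    if not _geom.strictly_contains(hist_outer, hist_lumen) \
            or not _geom.strictly_contains(us_outer, us_lumen):
        raise ValueError("lumen must lie strictly inside the outer contour")

    c_h = _geom.to_polygon(hist_lumen).centroid
    c_u = _geom.to_polygon(us_lumen).centroid
    center_h = np.array([c_h.x, c_h.y])
    center_u = np.array([c_u.x, c_u.y])
    a_h = _anchor_index(hist_lumen, hist_outer)
    a_u = _anchor_index(us_lumen, us_outer)

    src = np.vstack([_landmarks(hist_lumen, a_h, center_h, n_landmarks),
                     _landmarks(hist_outer, a_h, center_h, n_landmarks)])
    dst = np.vstack([_landmarks(us_lumen, a_u, center_u, n_landmarks),
                     _landmarks(us_outer, a_u, center_u, n_landmarks)])
    rbf = RBFInterpolator(src, dst, kernel="thin_plate_spline",
                          smoothing=regularization, degree=1)
    return ContourTransform(src, dst, regularization, rbf)


def apply_transform(transform: ContourTransform, contours) -> list:
    """Map contours (list of closed polylines, or a single one) pointwise.

    Warns when points fall far outside the landmark hull (extrapolation).
    """
    single = isinstance(contours, np.ndarray) and np.asarray(contours).ndim == 2
    items = [contours] if single else list(contours)
    out = [transform(np.asarray(c, float)) for c in items]
    return out
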