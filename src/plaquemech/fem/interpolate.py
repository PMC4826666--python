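"""Barycentric interpolation of nodal fields on triangle meshes.

Quadratic elements are split into their four corner/midside linear
sub-triangles, so interpolation is piecewise linear, exact at every node,
and works on either the reference or a deformed node configuration (pass
``nodes = mesh.nodes + u``).  Point location uses a k-d tree over
sub-triangle centroids with a barycentric containment test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from plaquemech.fem.mesh import Mesh

__all__ = ["FieldInterpolator", "interpolate_displacement"]


class FieldInterpolator:
    """Piecewise-linear interpolator of per-node values over triangles.

    Parameters
    ----------
    nodes : (N, 2) node coordinates (mm).
    triangles : (M, 3) node indices (linear triangles).
    values : (N,) or (N, k) nodal values.
    """

    def __init__(self, nodes: np.ndarray, triangles: np.ndarray,
                 values: np.ndarray, tol: float = 1e-9):
        self.nodes = np.asarray(nodes, float)
        self.tris = np.asarray(triangles, np.int64)
        self.values = np.asarray(values, float)
        self.tol = tol
        p = self.nodes[self.tris]
        self._origin = p[:, 0]
        T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=-1)
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        keep = np.abs(det) > 1e-14
        self._keep_idx = np.nonzero(keep)[0]
        self._Tinv = np.linalg.inv(T[keep])
        self._tree = cKDTree(p[keep].mean(axis=1))
        self._max_edge = np.sqrt(np.abs(det[keep])).max() * 2.0

    def locate(self, points: np.ndarray, k: int = 12):
        """Containing sub-triangle index and barycentric coords per point.

        Returns (tri_index, bary (n, 3)); tri_index = -1 for points outside
        the triangulation.
        """
        pts = np.asarray(points, float).reshape(-1, 2)
        n = len(pts)
        kq = min(k, len(self._keep_idx))
        _, cand = self._tree.query(pts, k=kq)
        cand = np.atleast_2d(cand)
        tri_idx = np.full(n, -1, dtype=np.int64)
        bary = np.zeros((n, 3))
        remaining = np.arange(n)
        for col in range(cand.shape[1]):
            if len(remaining) == 0:
                break
            c = cand[remaining, col]
            d = pts[remaining] - self._origin[self._keep_idx[c]]
            lm = np.einsum("nij,nj->ni", self._Tinv[c], d)
            l0 = 1.0 - lm.sum(axis=1)
            ok = (lm[:, 0] >= -self.tol) & (lm[:, 1] >= -self.tol) & (l0 >= -self.tol)
            hit = remaining[ok]
            tri_idx[hit] = self._keep_idx[c[ok]]
            bary[hit, 0] = l0[ok]
            bary[hit, 1:] = lm[ok]
            remaining = remaining[~ok]
        return tri_idx, bary

    def __call__(self, points: np.ndarray, outside: str = "raise") -> np.ndarray:
        """Interpolate at points.

        ``outside`` controls points with no containing triangle: 'raise',
        'nan', or 'nearest' (value of the nearest mesh node — appropriate
        for points a hair outside a polygonal boundary).
        """
        pts = np.asarray(points, float).reshape(-1, 2)
        tri_idx, bary = self.locate(pts)
        missing = tri_idx < 0
        if missing.any() and outside == "raise":
            bad = pts[missing][0]
            raise ValueError(f"point {bad} lies outside the meshed domain")
        safe = np.where(tri_idx < 0, 0, tri_idx)
        vals = np.einsum("nc,nc...->n...", bary, self.values[self.tris[safe]])
        if missing.any():
            if outside == "nearest":
                node_tree = cKDTree(self.nodes)
                _, nearest = node_tree.query(pts[missing])
                vals[missing] = self.values[nearest]
            else:
                vals[missing] = np.nan
        return vals


def interpolate_displacement(solution, mesh: Mesh, points: np.ndarray,
                             deformed: bool = False,
                             outside: str = "raise") -> np.ndarray:
    """Displacement vectors (mm) at query points.

    With ``deformed=True`` the query points are interpreted in the deformed
    configuration at the solution's pressure (nodes moved by the solution's
    displacement before interpolation); otherwise in the reference
    configuration.  Exact at nodes; raises for points outside the domain.
    """
    u = solution.nodal_displacements if hasattr(solution, "nodal_displacements") \
        else np.asarray(solution, float)
    nodes = mesh.nodes + u if deformed else mesh.nodes
    interp = FieldInterpolator(nodes, mesh.subtriangles(), u)
    return interp(points, outside=outside)
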