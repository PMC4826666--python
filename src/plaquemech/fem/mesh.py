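"""Structured radial meshing of layered plaque cross-sections.

The plaque contours are star-shaped about the lumen centroid, so the tissue
and buffer are meshed as stacked radial rings of quadrilateral cells split
into triangles, then elevated to 6-node quadratic (P2) elements with
straight edges.  Region labels (intima / wall / buffer) follow the ring the
element was built in; calcium inclusions relabel tissue elements by majority
intersection area with the calcium polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from plaquemech import _geom
from plaquemech.errors import MeshingError
from plaquemech.phantom import PlaqueGeometry

REGIONS = ("intima", "wall", "calcium", "buffer")

_SUBTRI = np.array([[0, 3, 5], [3, 1, 4], [5, 4, 2], [3, 4, 5]])


@dataclass
class Mesh:
    """Quadratic triangle mesh with per-element region labels.

    nodes: (N, 2) mm.  elements: (nel, 6) node indices ordered
    (v0, v1, v2, m01, m12, m20) with CCW corners.  lumen_edges: (ne, 3)
    (start, mid, end) node triples traversing the lumen boundary CCW.
    fixed_nodes: indices clamped to zero displacement (buffer outer rim).
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray              # (nel,) strings from REGIONS
    lumen_edges: np.ndarray
    fixed_nodes: np.ndarray
    target_edge: float = 0.0

    def __post_init__(self):
        areas = self.corner_areas()
        if np.any(areas <= 0):
            raise MeshingError("mesh contains inverted or degenerate elements")
        if not set(np.unique(self.region)) <= set(REGIONS):
            raise MeshingError("unknown region label")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_areas(self) -> np.ndarray:
        """Signed areas of the corner (straight-edge) triangles."""
        p = self.nodes[self.elements[:, :3]]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :3]].mean(axis=1)

    def subtriangles(self) -> np.ndarray:
        """Split each P2 triangle into its 4 corner/midside linear triangles."""
        return self.elements[:, _SUBTRI].reshape(-1, 3)

    def region_mask(self, *names: str) -> np.ndarray:
        return np.isin(self.region, names)

    def region_area(self, *names: str) -> float:
        return float(np.abs(self.corner_areas()[self.region_mask(*names)]).sum())


def _ring_radii(geometry: PlaqueGeometry, theta: np.ndarray, buffer_thickness: float):
    c = geometry.center
    r_l = _geom.radius_profile(geometry.lumen_contour, c, theta)
    r_i = _geom.radius_profile(geometry.ima_contour, c, theta)
    r_o = _geom.radius_profile(geometry.outer_contour, c, theta)
    return r_l, r_i, r_o, r_o + buffer_thickness


def mesh_geometry(geometry: PlaqueGeometry,
                  target_edge: float = 0.2,
                  buffer_thickness: float = 2.0,
                  buffer_coarsening: float = 2.0) -> Mesh:
    """Mesh a plaque cross-section plus its surrounding buffer ring.

    ``target_edge`` (mm) sets the nominal element size in the tissue; the
    buffer is meshed ``buffer_coarsening`` times coarser.  Element count
    scales as ~area / target_edge².  Raises :class:`MeshingError` for
    degenerate contours.
    """
    if target_edge <= 0 or buffer_thickness <= 0:
        raise MeshingError("target_edge and buffer_thickness must be positive")
    center = geometry.center

    r_probe = _geom.radius_profile(geometry.ima_contour, center,
                                   np.linspace(0, 2 * np.pi, 256, endpoint=False))
    n_theta = max(32, int(np.ceil(2 * np.pi * r_probe.mean() / target_edge)))
    n_theta += n_theta % 2
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    r_l, r_i, r_o, r_b = _ring_radii(geometry, theta, buffer_thickness)
    if np.any(r_i - r_l <= 0) or np.any(r_o - r_i <= 0):
        raise MeshingError("contours are not strictly nested along every ray")

    n_int = max(2, int(np.ceil((r_i - r_l).mean() / target_edge)))
    n_wall = max(2, int(np.ceil((r_o - r_i).mean() / target_edge)))
    n_buf = max(2, int(np.ceil(buffer_thickness / (buffer_coarsening * target_edge))))

    # radial node rings: lumen -> ima -> outer -> buffer rim
    fractions = []
    for n_lay, lo, hi, reg in ((n_int, r_l, r_i, "intima"),
                               (n_wall, r_i, r_o, "wall"),
                               (n_buf, r_o, r_b, "buffer")):
        for k in range(n_lay):
            fractions.append((lo + (hi - lo) * k / n_lay, reg))
    fractions.append((r_b, "buffer"))
    radii = np.array([f[0] for f in fractions])          # (n_rings, n_theta)
    ring_region = [f[1] for f in fractions[:-1]]         # region of layer below ring k+1
    n_rings = len(radii)

    direction = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    nodes = (center[None, None, :] + radii[:, :, None] * direction[None, :, :])
    nodes = nodes.reshape(-1, 2)

    def nid(k, j):
        return k * n_theta + (j % n_theta)

    tris, regions = [], []
    for k in range(n_rings - 1):
        reg = ring_region[k]
        for j in range(n_theta):
            a, b = nid(k, j), nid(k, j + 1)
            c2, d = nid(k + 1, j + 1), nid(k + 1, j)
            if (j + k) % 2 == 0:
                tris += [[a, b, c2], [a, c2, d]]
            else:
                tris += [[a, b, d], [b, c2, d]]
            regions += [reg, reg]
    tris = np.array(tris, dtype=np.int64)
    regions = np.array(regions, dtype=object)

    # enforce CCW corner ordering
    p = nodes[tris]
    signed = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                    - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = signed < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    # relabel calcium by majority intersection area
    if geometry.calcium_regions:
        cent = nodes[tris].mean(axis=1)
        pts = nodes[tris]
        for calc in geometry.calcium_regions:
            poly = Polygon(calc)
            minx, miny, maxx, maxy = poly.bounds
            pad = 2 * target_edge
            near = ((cent[:, 0] > minx - pad) & (cent[:, 0] < maxx + pad)
                    & (cent[:, 1] > miny - pad) & (cent[:, 1] < maxy + pad)
                    & (regions != "buffer"))
            for e in np.nonzero(near)[0]:
                tri_poly = Polygon(pts[e])
                if poly.intersection(tri_poly).area >= 0.5 * tri_poly.area:
                    regions[e] = "calcium"

    # elevate to P2: one midside node per unique edge
    edge_mid = {}
    all_nodes = [nodes]
    next_id = len(nodes)
    elements = np.empty((len(tris), 6), dtype=np.int64)
    elements[:, :3] = tris
    mids = np.empty((len(tris), 3), dtype=np.int64)
    for e, (v0, v1, v2) in enumerate(tris):
        for s, (a, b) in enumerate(((v0, v1), (v1, v2), (v2, v0))):
            key = (a, b) if a < b else (b, a)
            m = edge_mid.get(key)
            if m is None:
                m = next_id
                edge_mid[key] = m
                all_nodes.append(0.5 * (nodes[a] + nodes[b]))
                next_id += 1
            mids[e, s] = m
    elements[:, 3:] = mids
    coords = np.vstack([all_nodes[0], np.array(all_nodes[1:])]) if len(all_nodes) > 1 \
        else all_nodes[0]

    # lumen boundary edges (ring 0), CCW with increasing theta
    lumen_edges = []
    for j in range(n_theta):
        a, b = nid(0, j), nid(0, j + 1)
        key = (a, b) if a < b else (b, a)
        lumen_edges.append((a, edge_mid[key], b))
    lumen_edges = np.array(lumen_edges, dtype=np.int64)

    # fixed nodes: outermost ring corners plus midside nodes on that ring
    rim_corners = set(range((n_rings - 1) * n_theta, n_rings * n_theta))
    fixed = set(rim_corners)
    for (a, b), m in edge_mid.items():
        if a in rim_corners and b in rim_corners:
            fixed.add(m)
    fixed = np.array(sorted(fixed), dtype=np.int64)

    return Mesh(coords, elements, regions.astype("U8"), lumen_edges, fixed,
                target_edge=target_edge)
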