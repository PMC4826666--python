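"""Synthetic plaque cross-sections, material maps and scatterer fields.

The phantom stands in for an excised atherosclerotic iliac artery mounted in
an inflation setup: a layered 2D cross-section (lumen, thickened intima,
media+adventitia fused as "wall"), optional stiff calcium inclusions near the
intima-media interface, surrounded by a soft buffer in the finite-element
model.  Eccentric plaques concentrate the intimal thickening on one side of
the vessel; the thick pole faces the transducer by default so the thickest
plaque section sits in the central ultrasound beam region.

All coordinates are mm, x lateral, y axial (depth below the transducer face).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import contains_xy

from plaquemech import _geom
from plaquemech.errors import GeometryFileError, InfeasibleGeometryError

__all__ = [
    "PlaqueGeometry",
    "MaterialMap",
    "ScattererField",
    "CalciumSpec",
    "make_vessel_geometry",
    "make_scatterers",
    "write_geometry",
    "read_geometry",
    "write_scatterers",
    "read_scatterers",
]


@dataclass
class PlaqueGeometry:
    """Layered 2D plaque cross-section.

    Contours are closed CCW polylines in mm (no repeated end vertex), nested
    strictly: lumen inside the intima-media interface (``ima_contour``)
    inside the outer vessel wall.  ``calcium_regions`` are closed polylines
    inside the tissue ring between lumen and outer contour.
    """

    lumen_contour: np.ndarray
    ima_contour: np.ndarray
    outer_contour: np.ndarray
    calcium_regions: list[np.ndarray] = field(default_factory=list)
    eccentric: bool = False

    def __post_init__(self):
        self.lumen_contour = _geom.ensure_ccw(np.asarray(self.lumen_contour, float))
        self.ima_contour = _geom.ensure_ccw(np.asarray(self.ima_contour, float))
        self.outer_contour = _geom.ensure_ccw(np.asarray(self.outer_contour, float))
        self.calcium_regions = [_geom.ensure_ccw(np.asarray(c, float))
                                for c in self.calcium_regions]
        self.validate()

    @property
    def center(self) -> np.ndarray:
        """Lumen centroid (mm)."""
        c = _geom.to_polygon(self.lumen_contour).centroid
        return np.array([c.x, c.y])

    def validate(self) -> None:
        """Raise :class:`InfeasibleGeometryError` on broken invariants."""
        for name, c in [("lumen", self.lumen_contour), ("ima", self.ima_contour),
                        ("outer", self.outer_contour)]:
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 3:
                raise InfeasibleGeometryError(f"{name} contour is not a closed polyline")
            if not _geom.is_simple(c):
                raise InfeasibleGeometryError(f"{name} contour self-intersects")
        if not _geom.strictly_contains(self.ima_contour, self.lumen_contour):
            raise InfeasibleGeometryError("lumen is not strictly inside the intima-media interface")
        if not _geom.strictly_contains(self.outer_contour, self.ima_contour):
            raise InfeasibleGeometryError("intima-media interface is not strictly inside the outer wall")
        ring = _geom.to_polygon(self.outer_contour).difference(
            _geom.to_polygon(self.lumen_contour))
        for k, calc in enumerate(self.calcium_regions):
            if not _geom.is_simple(calc):
                raise InfeasibleGeometryError(f"calcium region {k} self-intersects")
            if not ring.buffer(1e-9).contains(_geom.to_polygon(calc)):
                raise InfeasibleGeometryError(
                    f"calcium region {k} is not inside the tissue between lumen and outer wall")

    def region_areas(self) -> dict:
        """Areas (mm²) of lumen, intima ring, wall ring and calcium."""
        a_l = _geom.shoelace_area(self.lumen_contour)
        a_i = _geom.shoelace_area(self.ima_contour)
        a_o = _geom.shoelace_area(self.outer_contour)
        a_c = sum(_geom.shoelace_area(c) for c in self.calcium_regions)
        return {"lumen": a_l, "intima": a_i - a_l, "wall": a_o - a_i, "calcium": a_c}


@dataclass
class MaterialMap:
    """Neo-Hookean shear moduli per region, kPa.

    ``C_calcium`` defaults to 1e5 kPa (calcium treated as effectively rigid);
    the buffer is far softer than any tissue so it only suppresses rigid-body
    motion.
    """

    C_wall: float
    C_intima: float
    C_calcium: float = 1.0e5
    C_buffer: float = 0.01

    def __post_init__(self):
        if min(self.C_wall, self.C_intima, self.C_calcium, self.C_buffer) <= 0:
            raise ValueError("all shear moduli must be positive")
        if self.C_calcium < max(self.C_wall, self.C_intima):
            raise ValueError("calcium must be at least as stiff as the tissue")
        if self.C_buffer >= min(self.C_wall, self.C_intima):
            raise ValueError("buffer must be softer than any tissue region")

    def modulus(self, region: str) -> float:
        return {"wall": self.C_wall, "intima": self.C_intima,
                "calcium": self.C_calcium, "buffer": self.C_buffer}[region]


@dataclass
class ScattererField:
    """Random acoustic scatterers: positions (N, 2) mm, reflectivities (N,)."""

    positions: np.ndarray
    amplitudes: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 2)
        self.amplitudes = np.asarray(self.amplitudes, float).reshape(-1)
        if len(self.positions) != len(self.amplitudes):
            raise ValueError("positions and amplitudes length mismatch")

    def __len__(self):
        return len(self.positions)


@dataclass
class CalciumSpec:
    """A single elliptical calcification adjacent to the intima-media
    interface.

    size_mm is the full tangential extent; the radial extent is
    ``size_mm * aspect``; ``angle_deg`` locates its centroid on the interface
    (math convention, measured from +x, thick pole at -90° by default).
    """

    size_mm: float = 0.4
    angle_deg: float = 90.0
    aspect: float = 0.5


def _thickness_profile(theta, t_max, ecc, theta0, floor_frac=0.02):
    """Cosine-modulated intimal thickness; ecc=0 uniform, ecc=1 one-sided."""
    t = t_max * ((1.0 - ecc) + ecc * 0.5 * (1.0 + np.cos(theta - theta0)))
    return np.maximum(t, floor_frac * t_max)


def make_vessel_geometry(lumen_radius: float,
                         wall_thickness: float,
                         intima_thickness_max: float,
                         eccentricity: float = 0.0,
                         calcium_spec: CalciumSpec | None = None,
                         n_vertices: int = 128,
                         seed: int | None = None,
                         center=(0.0, 6.0),
                         thick_angle_deg: float = -90.0,
                         irregularity: float = 0.0) -> PlaqueGeometry:
    """Generate a layered vessel cross-section.

    The lumen is a circle of ``lumen_radius``; the intima-media interface
    sits at lumen radius plus a cosine-modulated thickness profile peaking at
    ``intima_thickness_max`` at ``thick_angle_deg`` (toward the transducer by
    default); the outer wall adds a uniform ``wall_thickness``.
    ``eccentricity`` in [0, 1] moves the plaque from concentric to fully
    one-sided.  ``irregularity`` adds seeded smooth radial perturbations
    (fraction of the local radius) for less idealized shapes.

    Raises :class:`InfeasibleGeometryError` when the requested parameters
    would make contours touch or cross.
    """
    if lumen_radius <= 0 or wall_thickness <= 0 or intima_thickness_max <= 0:
        raise InfeasibleGeometryError("radii and thicknesses must be positive")
    if not 0.0 <= eccentricity <= 1.0:
        raise InfeasibleGeometryError("eccentricity must lie in [0, 1]")
    if n_vertices < 16:
        raise InfeasibleGeometryError("n_vertices must be at least 16")

    center = np.asarray(center, float)
    theta0 = np.deg2rad(thick_angle_deg)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    direction = np.stack([np.cos(theta), np.sin(theta)], axis=1)

    r_lumen = np.full(n_vertices, float(lumen_radius))
    t_int = _thickness_profile(theta, intima_thickness_max, eccentricity, theta0)
    r_ima = r_lumen + t_int
    r_outer = r_ima + wall_thickness

    if irregularity > 0.0:
        rng = np.random.default_rng(seed)
        for r in (r_lumen, r_ima, r_outer):
            # smooth periodic perturbation from a few low harmonics
            amp = irregularity * r.mean()
            for k in (2, 3, 5):
                phase = rng.uniform(0, 2 * np.pi)
                r += amp / k * np.cos(k * theta + phase)

    if np.any(r_ima - r_lumen <= 0) or np.any(r_outer - r_ima <= 0):
        raise InfeasibleGeometryError("contours would intersect for these parameters")

    lumen = center + r_lumen[:, None] * direction
    ima = center + r_ima[:, None] * direction
    outer = center + r_outer[:, None] * direction

    calcium = []
    if calcium_spec is not None:
        ang = np.deg2rad(calcium_spec.angle_deg)
        u_r = np.array([np.cos(ang), np.sin(ang)])
        u_t = np.array([-u_r[1], u_r[0]])
        r_at = float(_geom.radius_profile(ima, center, np.array([ang]))[0])
        c_pt = center + r_at * u_r
        poly = _geom.ellipse_polygon(
            c_pt, 0.5 * calcium_spec.size_mm * calcium_spec.aspect,
            0.5 * calcium_spec.size_mm, u_r)
        ring = _geom.to_polygon(outer).difference(_geom.to_polygon(lumen))
        if not ring.buffer(1e-9).contains(_geom.to_polygon(poly)):
            raise InfeasibleGeometryError(
                "calcium of this size does not fit in the tissue at the requested angle")
        calcium.append(poly)

    return PlaqueGeometry(lumen, ima, outer, calcium, eccentric=eccentricity > 0)


def make_scatterers(geometry: PlaqueGeometry,
                    density: float,
                    seed: int | None = None,
                    margin: float = 0.0,
                    include_lumen: bool = False) -> ScattererField:
    """Draw uniform random scatterers in the vessel tissue.

    The count is Poisson with mean ``density`` (per mm²) times the sampled
    region area; the region is the outer contour dilated by ``margin`` minus
    the lumen (the lumen is anechoic saline unless ``include_lumen``).
    Amplitudes are i.i.d. standard normal; reproducible for a fixed seed.
    """
    if density <= 0:
        raise ValueError("scatterer density must be positive (empty speckle otherwise)")
    region = _geom.to_polygon(geometry.outer_contour)
    if margin > 0:
        region = region.buffer(margin)
    if not include_lumen:
        region = region.difference(_geom.to_polygon(geometry.lumen_contour))
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density * region.area))
    minx, miny, maxx, maxy = region.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(max(2 * (n - got), 64), 2))
        keep = cand[contains_xy(region, cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - got)
        pts[got:got + take] = keep[:take]
        got += take
    amps = rng.standard_normal(n)
    return ScattererField(pts, amps, seed=seed)


# ---------------------------------------------------------------------------
# File I/O: geometry JSON, scatterers CSV
# ---------------------------------------------------------------------------

def write_geometry(geometry: PlaqueGeometry, path) -> None:
    """Write a geometry to JSON (named contour arrays in mm)."""
    payload = {
        "units": "mm",
        "lumen": geometry.lumen_contour.tolist(),
        "ima": geometry.ima_contour.tolist(),
        "outer": geometry.outer_contour.tolist(),
        "calcium": [c.tolist() for c in geometry.calcium_regions],
        "eccentric": bool(geometry.eccentric),
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry(path) -> PlaqueGeometry:
    """Read a geometry JSON written by :func:`write_geometry`.

    Raises :class:`GeometryFileError` on malformed files or broken geometric
    invariants (self-intersection, non-nested contours).
    """
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise GeometryFileError(f"cannot read geometry file {path}: {exc}") from exc
    try:
        return PlaqueGeometry(
            np.asarray(payload["lumen"], float),
            np.asarray(payload["ima"], float),
            np.asarray(payload["outer"], float),
            [np.asarray(c, float) for c in payload.get("calcium", [])],
            eccentric=bool(payload.get("eccentric", False)),
        )
    except (KeyError, TypeError, ValueError, InfeasibleGeometryError) as exc:
        raise GeometryFileError(f"malformed geometry in {path}: {exc}") from exc


def write_scatterers(field: ScattererField, path) -> None:
    """Write scatterers to CSV with columns x_mm, y_mm, amplitude."""
    data = np.column_stack([field.positions, field.amplitudes])
    np.savetxt(path, data, delimiter=",", header="x_mm,y_mm,amplitude", comments="")


def read_scatterers(path) -> ScattererField:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 3:
        raise ValueError(f"expected 3 columns in scatterer CSV {path}")
    return ScattererField(data[:, :2], data[:, 2])
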