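"""Legacy-VTK ASCII export of meshes and nodal fields for visualization.

The quadratic triangles map directly onto VTK's quadratic-triangle cell
(type 22, corners then midsides).  The writer emits the small legacy text
dialect that every VTK-based viewer reads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from plaquemech.fem.mesh import Mesh

__all__ = ["write_vtk"]

_REGION_CODE = {"intima": 1, "wall": 2, "calcium": 3, "buffer": 0}


def write_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Write the mesh (and optional per-node vector/scalar fields) to a
    legacy ASCII VTK file; element region labels go out as cell data."""
    lines = ["# vtk DataFile Version 3.0", "plaquemech mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0.0")
    nel = mesh.n_elements
    lines.append(f"CELLS {nel} {nel * 7}")
    for el in mesh.elements:
        lines.append("6 " + " ".join(str(int(i)) for i in el))
    lines.append(f"CELL_TYPES {nel}")
    lines.extend(["22"] * nel)
    lines.append(f"CELL_DATA {nel}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(_REGION_CODE[r]) for r in mesh.region)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, float)
            if values.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in values)
            else:
                lines.append(f"VECTORS {name} double")
                for row in values:
                    vx, vy = row[:2]
                    lines.append(f"{vx:.9g} {vy:.9g} 0.0")
    Path(path).write_text("\n".join(lines) + "\n")
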