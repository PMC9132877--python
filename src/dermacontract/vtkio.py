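"""Legacy-VTK ASCII export of the mesh and nodal fields, for inspection."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtk"]


def write_vtk(path, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the triangulation plus nodal scalar/vector/tensor fields.

    Scalars are (N,), vectors (N, 2) (padded with z = 0), symmetric tensors
    (N, 3) in (11, 22, 12) order written as full 3x3 tensors.
    """
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "dermacontract fields",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            elif arr.shape[1] == 2:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr)
            elif arr.shape[1] == 3:  # symmetric 2x2 Voigt (11, 22, 12)
                lines.append(f"TENSORS {name} double")
                for a, b, c in arr:
                    lines.append(f"{a:.10g} {c:.10g} 0")
                    lines.append(f"{c:.10g} {b:.10g} 0")
                    lines.append("0 0 0")
            else:
                raise ValueError(f"unsupported field shape {arr.shape} for {name!r}")
    path.write_text("\n".join(lines) + "\n")
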