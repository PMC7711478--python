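"""Legacy-VTK (ASCII unstructured grid) writer for meshes and solutions.

The legacy format is plain text and readable by ParaView/VisIt; only
the subset needed here (hexahedral cells, point vectors, cell scalars)
is emitted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .mesh import HexMesh

_VTK_HEX = 12


def write_legacy_vtk(
    mesh: HexMesh,
    path: str | Path,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
    title: str = "enterospring model",
) -> None:
    """Write the mesh (+ optional nodal/cell fields) as legacy VTK ASCII.

    Point arrays may be (N,) scalars or (N, 3) vectors; cell arrays
    (E,) scalars or (E, 3) vectors.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}")
    for e in mesh.elems:
        lines.append("8 " + " ".join(str(int(n)) for n in e))
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines.extend([str(_VTK_HEX)] * mesh.n_elems)

    def emit_fields(data: Mapping[str, np.ndarray], n: int, kind: str):
        lines.append(f"{kind} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                for v in arr:
                    lines.append(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr.ravel())

    if point_data:
        emit_fields(point_data, mesh.n_nodes, "POINT_DATA")
    if cell_data:
        emit_fields(cell_data, mesh.n_elems, "CELL_DATA")
    Path(path).write_text("\n".join(lines) + "\n")


def solution_cell_data(sol) -> dict[str, np.ndarray]:
    """Cell-averaged cylindrical stress/strain components for VTK export."""
    from .postprocess import _cylindrical_rotation, gauss_point_fields

    fields = gauss_point_fields(sol)
    Q = _cylindrical_rotation(fields["X"])
    E_cyl = np.einsum("egki,egkl,eglj->egij", Q, fields["E"], Q)
    S_cyl = np.einsum("egki,egkl,eglj->egij", Q, fields["sigma"], Q)
    out = {}
    for name, arr in (("E", E_cyl), ("S", S_cyl)):
        for label, (i, j) in (("RR", (0, 0)), ("TT", (1, 1)), ("ZZ", (2, 2))):
            out[f"{name}_{label}"] = arr[:, :, i, j].mean(axis=1)
    return out
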