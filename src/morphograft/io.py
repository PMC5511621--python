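"""Snapshot, time-series, and checkpoint output.

Snapshots are legacy-ASCII VTK unstructured grids (one file per epoch, all
nodal fields attached); the scalar time series goes to CSV via pandas; and
checkpoint/restart uses an HDF5 container.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import Mesh, StateFields

__all__ = ["write_vtk", "write_timeseries", "save_checkpoint", "load_checkpoint"]


def write_vtk(path: str | Path, mesh: Mesh, state: StateFields, current: bool = True) -> None:
    """Write the mesh and all nodal fields as a legacy-ASCII VTK unstructured grid."""
    coords = mesh.cur_coords if current else mesh.ref_coords
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "morphograft snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for p in coords:
        lines.append(f"{p[0]:.10g} {p[1]:.10g} 0")
    lines.append(f"CELLS {m} {4 * m}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE
    lines.append(f"POINT_DATA {n}")
    scalars = {
        "fibroblasts": state.N, "myofibroblasts": state.M, "signal": state.c,
        "collagen": state.rho, "eps22": state.eps22, "eps23": state.eps23,
        "eps33": state.eps33, "graft_marker": state.graft_marker,
    }
    for name, vals in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in vals)
    for name, vals in (("displacement", state.u), ("velocity", state.v)):
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def write_timeseries(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


_STATE_KEYS = ("N", "M", "c", "rho", "u", "v", "eps22", "eps23", "eps33", "graft_marker")


def save_checkpoint(path: str | Path, mesh: Mesh, state: StateFields, time: float) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["time"] = time
        f.attrs["half_width"] = mesh.half_width
        g = f.create_group("mesh")
        g.create_dataset("ref_coords", data=mesh.ref_coords)
        g.create_dataset("cur_coords", data=mesh.cur_coords)
        g.create_dataset("triangles", data=mesh.triangles)
        g.create_dataset("boundary_mask", data=mesh.boundary_mask)
        g.create_dataset("level", data=mesh.level)
        g.create_dataset("parent", data=mesh.parent)
        g.create_dataset("vertex_parents", data=mesh.vertex_parents)
        s = f.create_group("state")
        for k in _STATE_KEYS:
            s.create_dataset(k, data=getattr(state, k))


def load_checkpoint(path: str | Path) -> tuple[Mesh, StateFields, float]:
    with h5py.File(path, "r") as f:
        g = f["mesh"]
        mesh = Mesh(
            ref_coords=g["ref_coords"][()],
            cur_coords=g["cur_coords"][()],
            triangles=g["triangles"][()],
            boundary_mask=g["boundary_mask"][()],
            level=g["level"][()],
            parent=g["parent"][()],
            vertex_parents=g["vertex_parents"][()],
            half_width=float(f.attrs["half_width"]),
        )
        s = f["state"]
        vals = {k: s[k][()] for k in _STATE_KEYS}
        state = StateFields(**vals)
        return mesh, state, float(f.attrs["time"])
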