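"""Text I/O: Abaqus-.inp subset, ASCII VTU export, YAML configuration.

The .inp subset covers *NODE, *ELEMENT (C3D4/C3D10), *NSET and *ELSET
with one-based ids, enough to round-trip the package's meshes.  VTU
output is ASCII XML (UnstructuredGrid) with optional per-node vectors
and per-element scalars; the 10-node connectivity transfers unchanged
because the mid-side ordering matches VTK's quadratic tetra.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .mesh import TetMesh

__all__ = ["write_inp", "read_inp", "write_vtu", "write_load_case_inp",
           "load_yaml_config"]

_VTK_CELL = {4: 10, 10: 24}  # tetra, quadratic tetra


def write_inp(mesh: TetMesh, path) -> None:
    """Write the mesh as an Abaqus-input subset (one-based ids)."""
    etype = "C3D4" if mesh.order == "linear" else "C3D10"
    lines = ["*HEADING", "mandifem surrogate mandible mesh", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.10g}, {y:.10g}, {z:.10g}")
    for label in sorted(set(mesh.material_labels)):
        ids = np.nonzero(mesh.material_labels == label)[0]
        lines.append(f"*ELEMENT, TYPE={etype}, ELSET=MAT_{label}")
        for e in ids:
            conn = ", ".join(str(n + 1) for n in mesh.elements[e])
            lines.append(f"{e + 1}, {conn}")
    for name, ids in sorted(mesh.node_sets.items()):
        lines.append(f"*NSET, NSET={name}")
        lines.extend(_chunk_ids(ids + 1))
    for name, ids in sorted(mesh.element_sets.items()):
        lines.append(f"*ELSET, ELSET={name}")
        lines.extend(_chunk_ids(ids + 1))
    Path(path).write_text("\n".join(lines) + "\n")


def _chunk_ids(ids, per_line: int = 16):
    ids = list(int(i) for i in ids)
    for lo in range(0, len(ids), per_line):
        yield ", ".join(str(i) for i in ids[lo:lo + per_line])


def read_inp(path) -> TetMesh:
    """Parse the .inp subset written by :func:`write_inp`."""
    nodes, elems, labels = [], {}, {}
    node_sets, elem_sets = {}, {}
    section, current, etype = None, None, None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            parts = [p.strip() for p in line.split(",")]
            key = parts[0].upper()
            opts = {}
            for p in parts[1:]:
                if "=" in p:
                    k, v = p.split("=", 1)
                    opts[k.strip().upper()] = v.strip()
            if key == "*NODE":
                section = "node"
            elif key == "*ELEMENT":
                section = "element"
                etype = opts.get("TYPE", "C3D4").upper()
                current = opts.get("ELSET", "MAT_default")
            elif key == "*NSET":
                section = "nset"
                current = opts["NSET"]
                node_sets[current] = []
            elif key == "*ELSET":
                section = "elset"
                current = opts["ELSET"]
                elem_sets[current] = []
            else:
                section = None
            continue
        vals = [v.strip() for v in line.split(",") if v.strip()]
        if section == "node":
            nodes.append([float(v) for v in vals[1:4]])
        elif section == "element":
            eid = int(vals[0]) - 1
            elems[eid] = [int(v) - 1 for v in vals[1:]]
            labels[eid] = current.removeprefix("MAT_")
        elif section == "nset":
            node_sets[current].extend(int(v) - 1 for v in vals)
        elif section == "elset":
            elem_sets[current].extend(int(v) - 1 for v in vals)
    order = "quadratic" if etype == "C3D10" else "linear"
    eids = sorted(elems)
    connectivity = np.asarray([elems[e] for e in eids], dtype=np.int64)
    material = np.asarray([labels[e] for e in eids], dtype=object)
    return TetMesh(nodes=np.asarray(nodes), elements=connectivity,
                   order=order,
                   node_sets={k: np.asarray(v, dtype=np.int64)
                              for k, v in node_sets.items()},
                   element_sets={k: np.asarray(v, dtype=np.int64)
                                 for k, v in elem_sets.items()},
                   material_labels=material)


def write_vtu(mesh: TetMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """ASCII XML UnstructuredGrid export for visualization."""
    nn = mesh.elements.shape[1]
    n_cells = mesh.n_elements
    out = []
    out.append('<?xml version="1.0"?>')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" '
               'byte_order="LittleEndian">')
    out.append("  <UnstructuredGrid>")
    out.append(f'    <Piece NumberOfPoints="{mesh.n_nodes}" '
               f'NumberOfCells="{n_cells}">')
    out.append("      <Points>")
    out.append('        <DataArray type="Float64" NumberOfComponents="3" '
               'format="ascii">')
    for p in mesh.nodes:
        out.append(f"          {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    out.append("        </DataArray>")
    out.append("      </Points>")
    out.append("      <Cells>")
    out.append('        <DataArray type="Int64" Name="connectivity" '
               'format="ascii">')
    for e in mesh.elements:
        out.append("          " + " ".join(str(n) for n in e))
    out.append("        </DataArray>")
    out.append('        <DataArray type="Int64" Name="offsets" format="ascii">')
    out.append("          " + " ".join(str(nn * (i + 1))
                                       for i in range(n_cells)))
    out.append("        </DataArray>")
    out.append('        <DataArray type="UInt8" Name="types" format="ascii">')
    out.append("          " + " ".join(str(_VTK_CELL[nn])
                                       for _ in range(n_cells)))
    out.append("        </DataArray>")
    out.append("      </Cells>")
    out.append("      <PointData>")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        out.append(f'        <DataArray type="Float64" Name="{name}" '
                   f'NumberOfComponents="{ncomp}" format="ascii">')
        for row in np.atleast_2d(arr.reshape(len(arr), -1)):
            out.append("          " + " ".join(f"{v:.10g}" for v in row))
        out.append("        </DataArray>")
    out.append("      </PointData>")
    out.append("      <CellData>")
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, dtype=float).reshape(n_cells, -1)
        out.append(f'        <DataArray type="Float64" Name="{name}" '
                   f'NumberOfComponents="{arr.shape[1]}" format="ascii">')
        for row in arr:
            out.append("          " + " ".join(f"{v:.10g}" for v in row))
        out.append("        </DataArray>")
    out.append("      </CellData>")
    out.append("    </Piece>")
    out.append("  </UnstructuredGrid>")
    out.append("</VTKFile>")
    Path(path).write_text("\n".join(out) + "\n")


def write_load_case_inp(load_case, path) -> None:
    """Export nodal loads / boundary conditions as *CLOAD / *BOUNDARY."""
    lines = ["*CLOAD"]
    for node in sorted(load_case.nodal_forces):
        f = load_case.nodal_forces[node]
        for ax in range(3):
            if f[ax] != 0.0:
                lines.append(f"{node + 1}, {ax + 1}, {f[ax]:.10g}")
    lines.append("*BOUNDARY")
    for node, ax in load_case.fixed_dofs:
        lines.append(f"{node + 1}, {ax + 1}, {ax + 1}, 0.")
    Path(path).write_text("\n".join(lines) + "\n")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
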