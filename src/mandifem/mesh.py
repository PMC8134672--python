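"""Tetrahedral mesh container and elementary mesh operations.

Meshes are stored as flat numpy arrays: node coordinates in millimetres,
connectivity as 4-node (linear, C3D4-style) or 10-node (quadratic,
C3D10-style) tuples, plus named node/element sets and a per-element
material label.  The 10-node convention places mid-side nodes on edges
(1-2), (2-3), (3-1), (1-4), (2-4), (3-4) of the corner tetrahedron,
matching both the Abaqus C3D10 and the VTK quadratic-tetra ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TetMesh",
    "MeshError",
    "tet_volumes",
    "linear_to_quadratic",
    "box_mesh",
    "hex_grid_to_tets",
    "element_adjacency",
]

# edge list of a corner tet in mid-side order (local corner indices)
TET_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))


class MeshError(ValueError):
    """Raised for invalid mesh topology or degenerate geometry."""


@dataclass
class TetMesh:
    """Tetrahedral mesh with named sets and per-element material labels.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    elements : (n_elems, 4|10) int array
    order : "linear" or "quadratic"
    node_sets, element_sets : name -> sorted int arrays
    material_labels : (n_elems,) array of material names
    metadata : free-form provenance (generation parameters, warnings...)
    """

    nodes: np.ndarray
    elements: np.ndarray
    order: str = "linear"
    node_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    material_labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise MeshError("elements must be (n, 4) or (n, 10)")
        expected = "linear" if self.elements.shape[1] == 4 else "quadratic"
        if self.order != expected:
            raise MeshError(f"order {self.order!r} inconsistent with "
                            f"{self.elements.shape[1]}-node connectivity")
        if self.material_labels is None:
            self.material_labels = np.full(len(self.elements), "default",
                                           dtype=object)
        self.material_labels = np.asarray(self.material_labels, dtype=object)
        if len(self.material_labels) != len(self.elements):
            raise MeshError("one material label per element required")
        self.node_sets = {k: np.asarray(v, dtype=np.int64)
                          for k, v in self.node_sets.items()}
        self.element_sets = {k: np.asarray(v, dtype=np.int64)
                             for k, v in self.element_sets.items()}

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_connectivity(self) -> np.ndarray:
        """First four (corner) nodes of every element."""
        return self.elements[:, :4]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.corner_connectivity())

    def volume(self) -> float:
        return float(self.volumes().sum())

    def centroids(self) -> np.ndarray:
        """Corner-based element centroids."""
        return self.nodes[self.corner_connectivity()].mean(axis=1)

    def node_set(self, name: str) -> np.ndarray:
        try:
            return self.node_sets[name]
        except KeyError:
            raise MeshError(f"node set {name!r} not present in mesh") from None

    def element_set(self, name: str) -> np.ndarray:
        try:
            return self.element_sets[name]
        except KeyError:
            raise MeshError(f"element set {name!r} not present in mesh") from None

    # -- validity ---------------------------------------------------------
    def validate(self) -> None:
        """Raise MeshError on inverted elements, orphan nodes, bad sets."""
        if self.elements.min(initial=0) < 0 or \
                self.elements.max(initial=-1) >= self.n_nodes:
            raise MeshError("connectivity references nonexistent nodes")
        vols = self.volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise MeshError(f"element {bad} has non-positive volume {vols[bad]:g}")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise MeshError(f"{int((~used).sum())} orphan node(s)")
        for name, idx in self.node_sets.items():
            if len(idx) == 0:
                raise MeshError(f"node set {name!r} is empty")
            if idx.min() < 0 or idx.max() >= self.n_nodes:
                raise MeshError(f"node set {name!r} out of range")
        for name, idx in self.element_sets.items():
            if len(idx) == 0:
                raise MeshError(f"element set {name!r} is empty")
            if idx.min() < 0 or idx.max() >= self.n_elements:
                raise MeshError(f"element set {name!r} out of range")

    def copy(self) -> "TetMesh":
        return TetMesh(
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            order=self.order,
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_sets={k: v.copy() for k, v in self.element_sets.items()},
            material_labels=self.material_labels.copy(),
            metadata=dict(self.metadata),
        )


def tet_volumes(nodes: np.ndarray, conn: np.ndarray) -> np.ndarray:
    """Signed volumes of 4-node tets (positive for right-handed ordering)."""
    p = nodes[conn]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def linear_to_quadratic(mesh: TetMesh) -> TetMesh:
    """Convert 4-node tets to 10-node tets by inserting shared edge midpoints.

    Element count is unchanged; node sets are extended so that a mid-side
    node whose two edge endpoints both belong to a set joins that set.
    """
    if mesh.order != "linear":
        raise MeshError("mesh is already quadratic")
    conn = mesh.elements
    n_old = mesh.n_nodes
    # unique edges, deterministic ordering
    edges = np.concatenate([conn[:, [a, b]] for a, b in TET_EDGES])
    edges = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    nodes = np.vstack([mesh.nodes, mid])
    mid_ids = n_old + inverse.reshape(len(TET_EDGES), -1).T  # (n_elem, 6)
    elements = np.hstack([conn, mid_ids])

    node_sets = {}
    for name, idx in mesh.node_sets.items():
        member = np.zeros(n_old, dtype=bool)
        member[idx] = True
        on_edge = member[uniq[:, 0]] & member[uniq[:, 1]]
        extra = n_old + np.nonzero(on_edge)[0]
        node_sets[name] = np.concatenate([idx, extra])
    return TetMesh(
        nodes=nodes,
        elements=elements,
        order="quadratic",
        node_sets=node_sets,
        element_sets={k: v.copy() for k, v in mesh.element_sets.items()},
        material_labels=mesh.material_labels.copy(),
        metadata=dict(mesh.metadata),
    )


def hex_grid_to_tets(grid_shape, node_index) -> np.ndarray:
    """Split an (nx, ny, nz)-cell structured hex grid into 6 tets per cell.

    ``node_index(i, j, k)`` maps grid vertices to global node ids.  All
    cells are split around the main diagonal (i,j,k)-(i+1,j+1,k+1); the
    face diagonals of neighbouring cells then coincide, giving a
    conforming mesh.
    """
    nx, ny, nz = grid_shape
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                v = [node_index(i, j, k), node_index(i + 1, j, k),
                     node_index(i + 1, j + 1, k), node_index(i, j + 1, k),
                     node_index(i, j, k + 1), node_index(i + 1, j, k + 1),
                     node_index(i + 1, j + 1, k + 1), node_index(i, j + 1, k + 1)]
                for t in _HEX_TO_TETS:
                    tets.append([v[t[0]], v[t[1]], v[t[2]], v[t[3]]])
    return np.asarray(tets, dtype=np.int64)


# 6-tet split of a hex (bottom face 0123 CCW seen from above, top 4567),
# all tets share the 0-6 diagonal; orientation gives positive volumes for
# a right-handed cell.
_HEX_TO_TETS = (
    (0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
    (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6),
)


def box_mesh(lengths, divisions, origin=(0.0, 0.0, 0.0),
             material: str = "default") -> TetMesh:
    """Structured tet mesh of an axis-aligned box.

    Face node sets ``x0, x1, y0, y1, z0, z1`` are attached.  Used by the
    verification oracles (patch test, cantilever, tied blocks).
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elements = hex_grid_to_tets((nx, ny, nz), nid)
    ii, jj, kk = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                             np.arange(nz + 1), indexing="ij")
    flat = (ii * (ny + 1) + jj) * (nz + 1) + kk
    node_sets = {
        "x0": flat[0].ravel(), "x1": flat[-1].ravel(),
        "y0": flat[:, 0].ravel(), "y1": flat[:, -1].ravel(),
        "z0": flat[:, :, 0].ravel(), "z1": flat[:, :, -1].ravel(),
    }
    labels = np.full(len(elements), material, dtype=object)
    return TetMesh(nodes=nodes, elements=elements, node_sets=node_sets,
                   material_labels=labels)


def element_adjacency(mesh: TetMesh, elems: Iterable[int] | None = None
                      ) -> csr_matrix:
    """Face-adjacency graph of (a subset of) the corner tets."""
    conn = mesh.corner_connectivity()
    ids = np.arange(mesh.n_elements) if elems is None else np.asarray(list(elems))
    faces = {}
    rows, cols = [], []
    for e in ids:
        a, b, c, d = conn[e]
        for f in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
            key = tuple(sorted(f))
            other = faces.pop(key, None)
            if other is None:
                faces[key] = e
            else:
                rows.append(other)
                cols.append(e)
    n = mesh.n_elements
    data = np.ones(len(rows))
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    return adj + adj.T


def count_components(mesh: TetMesh, elems: Iterable[int]) -> int:
    """Number of face-connected components among the given elements."""
    ids = np.asarray(list(elems))
    adj = element_adjacency(mesh, ids)
    sub = adj[ids][:, ids]
    n, _ = connected_components(sub, directed=False)
    return n
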