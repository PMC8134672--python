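"""Small-strain linear-elastic solver for 4- and 10-node tetrahedra.

Assembly is vectorized and chunked; constant-strain tets use exact
single-point integration, quadratic tets a 4-point Gauss rule (exact for
their stiffness on straight-edged elements, which is all the package
generates - mid-side nodes always sit at edge midpoints, so the
isoparametric map stays affine).  Dirichlet constraints are imposed by
row/column elimination, tie constraints by eliminating slave DOFs onto
their masters (translational node-to-node rigid links).  The sparse LU
factorization of the constrained operator is the default solve path;
assembly ordering is fixed, so repeated runs are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh
from .materials import MaterialCard

__all__ = [
    "FieldResult",
    "StiffnessOperator",
    "SingularSystemError",
    "TieError",
    "elasticity_matrix",
    "assemble_stiffness",
    "apply_ties",
    "solve_static",
    "recover_fields",
    "von_mises_stress",
    "uniform_traction",
]

# 4-point Gauss rule on the reference tetrahedron (degree-2 exact)
_GA, _GB = 0.5854101966249685, 0.1381966011250105
_GAUSS = np.array([
    [_GA, _GB, _GB], [_GB, _GA, _GB], [_GB, _GB, _GA], [_GB, _GB, _GB]])

_CHUNK = 8192


class SingularSystemError(RuntimeError):
    """Stiffness system is singular; boundary conditions leave rigid modes."""


class TieError(ValueError):
    """Invalid tie constraint specification."""


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic Hooke matrix, Voigt order (xx, yy, zz, xy, yz, zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _element_moduli(mesh: TetMesh, materials: Dict[str, MaterialCard]):
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    for label in np.unique(mesh.material_labels):
        try:
            card = materials[label]
        except KeyError:
            raise KeyError(f"material label {label!r} has no material card"
                           ) from None
        m = mesh.material_labels == label
        E[m], nu[m] = card.youngs_modulus, card.poissons_ratio
    return E, nu


def _corner_geometry(nodes, conn4):
    """Affine Jacobian data: gradients of barycentric coords and volumes."""
    p = nodes[conn4]
    M = p[:, 1:] - p[:, :1]            # (m, 3, 3) rows = edge vectors
    detM = np.linalg.det(M)
    vol = detM / 6.0
    Minv = np.linalg.inv(M)            # dxi/dx = Minv^T ... see below
    # grad lambda_i (i=1..3) as columns of Minv; grad lambda_0 = -sum
    g123 = np.transpose(Minv, (0, 2, 1))   # (m, 3(i), 3(xyz))? careful below
    # x - p0 = M^T xi  =>  xi = M^-T (x - p0)  =>  d xi_i / d x_j = Minv[j, i]
    g123 = np.transpose(Minv, (0, 2, 1))   # g123[e, i, j] = d xi_i / d x_j
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return grads, vol


def _strain_displacement(grads):
    """B matrices (m, 6, 3*nn) from shape gradients (m, nn, 3)."""
    m, nn, _ = grads.shape
    B = np.zeros((m, 6, 3 * nn))
    gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
    cols = np.arange(nn)
    B[:, 0, 3 * cols] = gx
    B[:, 1, 3 * cols + 1] = gy
    B[:, 2, 3 * cols + 2] = gz
    B[:, 3, 3 * cols] = gy
    B[:, 3, 3 * cols + 1] = gx
    B[:, 4, 3 * cols + 1] = gz
    B[:, 4, 3 * cols + 2] = gy
    B[:, 5, 3 * cols] = gz
    B[:, 5, 3 * cols + 2] = gx
    return B


def _tet10_shape_gradients(xi):
    """dN/d(lambda) chain-ruled to dN/d(xi) at one Gauss point -> (10, 4)->(10,3).

    Corner i has N = l_i (2 l_i - 1); mid-side node on edge (a, b) has
    N = 4 l_a l_b, edges ordered (0,1), (1,2), (2,0), (0,3), (1,3), (2,3).
    """
    l = np.array([1.0 - xi.sum(), xi[0], xi[1], xi[2]])
    dN_dl = np.zeros((10, 4))
    for i in range(4):
        dN_dl[i, i] = 4 * l[i] - 1
    from .mesh import TET_EDGES
    for e, (a, b) in enumerate(TET_EDGES):
        dN_dl[4 + e, a] = 4 * l[b]
        dN_dl[4 + e, b] = 4 * l[a]
    # l0 = 1 - xi1 - xi2 - xi3, l_i = xi_i
    return dN_dl[:, 1:] - dN_dl[:, :1]


_TET10_DNDXI = np.array([_tet10_shape_gradients(x) for x in _GAUSS])


def _quadratic_gauss_grads(nodes, conn10):
    """Per-Gauss-point physical shape gradients for straight TET10s.

    Returns (grads[(4, m, 10, 3)], vol[m]).
    """
    p = nodes[conn10[:, :4]]
    M = p[:, 1:] - p[:, :1]
    vol = np.linalg.det(M) / 6.0
    Minv = np.linalg.inv(M)            # d xi_i / d x_j = Minv[j, i]
    dxi_dx = np.transpose(Minv, (0, 2, 1))
    grads = np.einsum("gni,eij->genj", _TET10_DNDXI, dxi_dx)
    return np.transpose(grads, (1, 0, 2, 3)), vol


@dataclass
class StiffnessOperator:
    """Assembled (optionally tie-reduced) global stiffness."""

    mesh: TetMesh
    materials: Dict[str, MaterialCard]
    K: sp.csr_matrix                    # reduced coordinates
    transform: sp.csr_matrix | None = None   # full dofs = T @ reduced
    rep_dof: np.ndarray | None = None   # full dof -> reduced index
    dof_axis: np.ndarray | None = None  # reduced index -> axis

    @property
    def n_full_dofs(self) -> int:
        return 3 * self.mesh.n_nodes

    def reduced_index(self, node: int, axis: int) -> int:
        dof = 3 * node + axis
        return int(dof if self.rep_dof is None else self.rep_dof[dof])


def assemble_stiffness(mesh: TetMesh,
                       materials: Dict[str, MaterialCard]) -> StiffnessOperator:
    """Assemble the symmetric global stiffness (N/mm) of the mesh.

    Before constraints the operator annihilates exactly the six
    rigid-body modes.  Inverted elements raise; every material label must
    resolve to a card.
    """
    E, nu = _element_moduli(mesh, materials)
    vols = mesh.volumes()
    if np.any(vols <= 0):
        raise ValueError("mesh contains inverted (non-positive volume) "
                         "elements")
    n_dof = 3 * mesh.n_nodes
    conn = mesh.elements
    nn = conn.shape[1]
    rows, cols, vals = [], [], []
    for lo in range(0, mesh.n_elements, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, mesh.n_elements))
        c = conn[sl]
        D = np.zeros((c.shape[0], 6, 6))
        for e_i, (Ee, nue) in enumerate(zip(E[sl], nu[sl])):
            D[e_i] = elasticity_matrix(Ee, nue)
        if nn == 4:
            grads, vol = _corner_geometry(mesh.nodes, c)
            B = _strain_displacement(grads)
            Ke = np.einsum("eai,eab,ebj,e->eij", B, D, B, vol, optimize=True)
        else:
            grads, vol = _quadratic_gauss_grads(mesh.nodes, c)
            Ke = np.zeros((c.shape[0], 30, 30))
            for g in range(4):
                B = _strain_displacement(grads[:, g])
                Ke += np.einsum("eai,eab,ebj,e->eij", B, D, B, vol / 4.0,
                                optimize=True)
        edof = (3 * c[:, :, None] + np.arange(3)[None, None, :]).reshape(
            c.shape[0], 3 * nn)
        rows.append(np.repeat(edof, 3 * nn, axis=1).ravel())
        cols.append(np.tile(edof, (1, 3 * nn)).ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof)).tocsr()
    # exact symmetry regardless of summation order
    K = (K + K.T) * 0.5
    return StiffnessOperator(mesh=mesh, materials=materials, K=K)


def apply_ties(op: StiffnessOperator, tie_pairs,
               tolerance: float = 5.0) -> StiffnessOperator:
    """Eliminate slave DOFs through node-to-node rigid links.

    ``tie_pairs``: iterables of (slave_node, master_node[, distance]).
    Pairs farther apart than ``tolerance`` (mm) are rejected.  Masters
    must not themselves be slaves (no chains).  An empty list returns the
    operator unchanged.
    """
    pairs = list(tie_pairs)
    if not pairs:
        return op
    if op.transform is not None:
        raise TieError("operator already tie-reduced")
    mesh = op.mesh
    offending = []
    norm_pairs = []
    for p in pairs:
        s, m = int(p[0]), int(p[1])
        dist = float(p[2]) if len(p) > 2 else \
            float(np.linalg.norm(mesh.nodes[s] - mesh.nodes[m]))
        if dist > tolerance:
            offending.append((s, m, dist))
        norm_pairs.append((s, m))
    if offending:
        raise TieError(f"{len(offending)} tie pair(s) exceed the proximity "
                       f"tolerance {tolerance} mm: {offending[:5]}")
    slaves = {}
    for s, m in norm_pairs:
        if s in slaves and slaves[s] != m:
            raise TieError(f"node {s} is slave to multiple masters")
        slaves[s] = m
    for s, m in slaves.items():
        if m in slaves:
            raise TieError(f"tie chain: master node {m} is itself a slave")

    n_full = op.n_full_dofs
    master_of = np.arange(n_full)
    for s, m in slaves.items():
        master_of[3 * s:3 * s + 3] = np.arange(3 * m, 3 * m + 3)
    keep = np.nonzero(master_of == np.arange(n_full))[0]
    red_index = -np.ones(n_full, dtype=np.int64)
    red_index[keep] = np.arange(len(keep))
    rep = red_index[master_of]
    T = sp.csr_matrix((np.ones(n_full), (np.arange(n_full), rep)),
                      shape=(n_full, len(keep)))
    K_red = (T.T @ op.K @ T).tocsr()
    K_red = (K_red + K_red.T) * 0.5
    return StiffnessOperator(mesh=mesh, materials=op.materials, K=K_red,
                             transform=T, rep_dof=rep,
                             dof_axis=keep % 3)


@dataclass
class FieldResult:
    """Solved displacement, strain and stress fields.

    Strains are dimensionless (multiply by 1e6 for microstrain); stresses
    in MPa; principal strains sorted e1 >= e2 >= e3.
    """

    displacements: np.ndarray                 # (n_nodes, 3), mm
    element_strain: np.ndarray                # (m, 3, 3)
    element_stress: np.ndarray                # (m, 3, 3), MPa
    principal_strains: np.ndarray             # (m, 3), descending
    von_mises: np.ndarray                     # (m,), MPa
    reactions: Dict[Tuple[int, int], float] = field(default_factory=dict)
    info: dict = field(default_factory=dict)


def solve_static(op: StiffnessOperator, load_case) -> FieldResult:
    """Solve K u = f under the load case's constraints and recover fields.

    Raises SingularSystemError when the constraints leave rigid-body
    modes.  On success the global equilibrium residual
    |sum(applied) + sum(reactions)| / |sum(applied)| is below 1e-8 per
    axis and is stored in ``info["equilibrium_residual"]``.
    """
    n_red = op.K.shape[0]
    f_full = np.zeros(op.n_full_dofs)
    for node, fvec in load_case.nodal_forces.items():
        f_full[3 * node:3 * node + 3] += fvec
    f = f_full if op.transform is None else op.transform.T @ f_full

    fixed = sorted({op.reduced_index(n, ax) for n, ax in load_case.fixed_dofs})
    if not fixed:
        raise SingularSystemError(
            "no fixed DOFs: the system retains rigid-body modes; prescribe "
            "boundary conditions (e.g. condylar restraints) before solving")
    fixed = np.asarray(fixed, dtype=np.int64)
    free = np.ones(n_red, dtype=bool)
    free[fixed] = False
    free_idx = np.nonzero(free)[0]

    K_ff = op.K[free_idx][:, free_idx].tocsc()
    try:
        lu = spla.splu(K_ff)
    except RuntimeError as exc:
        raise SingularSystemError(
            f"stiffness factorization failed ({exc}); the prescribed "
            "boundary conditions are likely insufficient") from exc
    u = np.zeros(n_red)
    u[free_idx] = lu.solve(f[free_idx])
    if not np.all(np.isfinite(u)):
        raise SingularSystemError("non-finite solution; system is singular")

    residual = op.K @ u - f
    reactions_red = residual[fixed]
    # relative residual on the free set
    f_norm = np.linalg.norm(f[free_idx])
    rel = np.linalg.norm(residual[free_idx]) / f_norm if f_norm > 0 else 0.0
    if rel > 1e-6:
        raise SingularSystemError(
            f"relative residual {rel:.2e} after solve; boundary conditions "
            "insufficient or system ill-posed")

    axis_of = fixed % 3 if op.dof_axis is None else op.dof_axis[fixed]
    applied = np.array([f_full[a::3].sum() for a in range(3)])
    react_sum = np.array([reactions_red[axis_of == a].sum() for a in range(3)])
    scale = max(np.abs(applied).max(), 1e-30)
    eq_residual = float(np.abs(applied + react_sum).max() / scale)

    u_full = u if op.transform is None else op.transform @ u
    disp = u_full.reshape(-1, 3)
    result = recover_fields(disp, op.mesh, op.materials)
    # reactions reported at the representative (master) node of each fixed DOF
    reactions: Dict[Tuple[int, int], float] = {}
    for n, ax in load_case.fixed_dofs:
        r = op.reduced_index(n, ax)
        pos = np.searchsorted(fixed, r)
        key = (n, int(ax))
        reactions[key] = float(reactions_red[pos])
    result.reactions = reactions
    result.info.update({
        "equilibrium_residual": eq_residual,
        "relative_residual": float(rel),
        "applied_force": applied,
        "reaction_force": react_sum,
        "n_dofs": int(n_red),
    })
    assert eq_residual < 1e-8 or np.abs(applied).max() == 0, \
        f"global equilibrium violated: residual {eq_residual:.2e}"
    return result


def recover_fields(displacements: np.ndarray, mesh: TetMesh,
                   materials: Dict[str, MaterialCard]) -> FieldResult:
    """Element-constant strain/stress recovery from nodal displacements.

    Linear tets are constant-strain; for quadratic tets the four
    Gauss-point strains are averaged with equal (volume) weights.
    Principal strains are the sorted eigenvalues of the symmetric strain
    tensor; the von Mises stress comes from the stress deviator.
    """
    disp = np.asarray(displacements, dtype=float).reshape(mesh.n_nodes, 3)
    E, nu = _element_moduli(mesh, materials)
    conn = mesh.elements
    nn = conn.shape[1]
    m = mesh.n_elements
    strain_v = np.zeros((m, 6))
    for lo in range(0, m, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, m))
        c = conn[sl]
        ue = disp[c].reshape(c.shape[0], 3 * nn)
        if nn == 4:
            grads, _ = _corner_geometry(mesh.nodes, c)
            B = _strain_displacement(grads)
            strain_v[sl] = np.einsum("eij,ej->ei", B, ue)
        else:
            grads, _ = _quadratic_gauss_grads(mesh.nodes, c)
            acc = np.zeros((c.shape[0], 6))
            for g in range(4):
                B = _strain_displacement(grads[:, g])
                acc += np.einsum("eij,ej->ei", B, ue)
            strain_v[sl] = acc / 4.0

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = strain_v[:, :3].sum(axis=1)
    stress_v = np.empty_like(strain_v)
    stress_v[:, :3] = (lam * tr)[:, None] + 2 * mu[:, None] * strain_v[:, :3]
    stress_v[:, 3:] = mu[:, None] * strain_v[:, 3:]  # engineering shear

    def voigt_to_tensor(v):
        t = np.empty((len(v), 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = v[:, 0], v[:, 1], v[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = v[:, 3]
        t[:, 1, 2] = t[:, 2, 1] = v[:, 4]
        t[:, 0, 2] = t[:, 2, 0] = v[:, 5]
        return t

    strain_t = voigt_to_tensor(np.column_stack(
        [strain_v[:, :3], strain_v[:, 3:] / 2.0]))  # tensor shear
    stress_t = voigt_to_tensor(stress_v)
    principal = np.linalg.eigvalsh(strain_t)[:, ::-1]
    vm = von_mises_stress(stress_v)
    return FieldResult(displacements=disp, element_strain=strain_t,
                       element_stress=stress_t, principal_strains=principal,
                       von_mises=vm)


_TET_FACES = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))


def uniform_traction(mesh: TetMesh, nodes, traction) -> Dict[int, np.ndarray]:
    """Consistent nodal forces for a constant traction on a surface patch.

    ``nodes`` is a node-set name or node ids; every boundary triangle
    whose corners all belong to the patch receives the traction (N/mm^2).
    Linear faces lump area/3 to each corner; straight quadratic faces
    lump area/3 to each mid-side node (the consistent load vector of a
    T6 under constant traction), so constant-stress patch states are
    reproduced exactly by both element orders.
    """
    ids = mesh.node_set(nodes) if isinstance(nodes, str) else \
        np.asarray(list(nodes), dtype=np.int64)
    member = np.zeros(mesh.n_nodes, dtype=bool)
    member[ids] = True
    t = np.asarray(traction, dtype=float)
    conn = mesh.elements
    # boundary faces = corner triples appearing exactly once
    seen: Dict[tuple, tuple] = {}
    for e in range(mesh.n_elements):
        for fi, (a, b, c) in enumerate(_TET_FACES):
            key = tuple(sorted((conn[e, a], conn[e, b], conn[e, c])))
            if key in seen:
                del seen[key]
            else:
                seen[key] = (e, fi)
    from .mesh import TET_EDGES
    edge_local = {tuple(sorted(ed)): 4 + i for i, ed in enumerate(TET_EDGES)}
    forces: Dict[int, np.ndarray] = {}

    def add(n, f):
        forces[int(n)] = forces.get(int(n), np.zeros(3)) + f

    for key, (e, fi) in sorted(seen.items()):
        if not member[list(key)].all():
            continue
        loc = _TET_FACES[fi]
        p = mesh.nodes[[conn[e, loc[0]], conn[e, loc[1]], conn[e, loc[2]]]]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        share = t * (area / 3.0)
        if conn.shape[1] == 4:
            for a in loc:
                add(conn[e, a], share)
        else:
            for a, b in ((loc[0], loc[1]), (loc[1], loc[2]),
                         (loc[2], loc[0])):
                add(conn[e, edge_local[tuple(sorted((a, b)))]], share)
    return forces


def von_mises_stress(stress_voigt: np.ndarray) -> np.ndarray:
    """Von Mises stress from Voigt stresses (xx, yy, zz, xy, yz, zx)."""
    s = np.asarray(stress_voigt)
    d1 = s[:, 0] - s[:, 1]
    d2 = s[:, 1] - s[:, 2]
    d3 = s[:, 2] - s[:, 0]
    return np.sqrt(0.5 * (d1 ** 2 + d2 ** 2 + d3 ** 2)
                   + 3.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2))
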