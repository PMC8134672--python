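"""Shared fixtures: coarse surrogate meshes and solver scaffolding.

Session-scoped coarse meshes keep the suite fast; every geometric or
mechanical property they exercise is resolution-independent.
"""

from dataclasses import replace

import numpy as np
import pytest

from mandifem.anatomy import HUMAN_DEFAULTS, SHEEP_DEFAULTS, generate_mandible
from mandifem.materials import MaterialCard, material_registry
from mandifem.mesh import box_mesh
from mandifem.fem import uniform_traction
from mandifem.muscles import LoadCase


@pytest.fixture(scope="session")
def human_coarse():
    return generate_mandible(replace(HUMAN_DEFAULTS, target_edge_length=6.0))


@pytest.fixture(scope="session")
def sheep_coarse():
    return generate_mandible(replace(SHEEP_DEFAULTS, target_edge_length=8.0))


@pytest.fixture(scope="session")
def human_materials():
    return material_registry("human")


@pytest.fixture
def unit_material():
    return {"default": MaterialCard("default", 1000.0, 0.3)}


def uniaxial_case(mesh, sigma):
    """Uniaxial-stress load case on a box mesh: traction on z1, minimal BCs.

    The bottom face is fixed vertically only (free Poisson contraction);
    two corner nodes pin the remaining in-plane rigid modes.
    """
    lc = LoadCase()
    lc.nodal_forces = uniform_traction(mesh, "z1", (0.0, 0.0, sigma))
    z0 = mesh.node_set("z0")
    for n in z0:
        lc.fixed_dofs.append((int(n), 2))
    xyz = mesh.nodes[z0]
    n00 = z0[np.argmin(xyz[:, 0] + xyz[:, 1])]
    n10 = z0[np.argmin(-xyz[:, 0] + xyz[:, 1])]
    lc.fixed_dofs += [(int(n00), 0), (int(n00), 1), (int(n10), 1)]
    lc.fixed_dofs = sorted(set(lc.fixed_dofs))
    return lc


@pytest.fixture
def make_uniaxial_case():
    return uniaxial_case


@pytest.fixture
def small_box():
    return box_mesh((1.0, 1.0, 2.0), (2, 2, 4))
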