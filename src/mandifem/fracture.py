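"""Fracture scenarios: granulation-filled gap plus miniplate fixation.

A simple fracture is modelled as a material swap: every element whose
centroid lies within half the gap width of a transverse plane is
reassigned to the very compliant granulation tissue (1 MPa), emulating
the earliest healing phase.  Connectivity is untouched - no mesh
splitting or contact.  Fixation then appends two 4-hole miniplates with
monocortical screws on the buccal side, bonded by node-to-node tie
pairs (plate-screw and screw-cortical bone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .mesh import TetMesh, MeshError, element_adjacency
from .anatomy import (AnatomyParams, fracture_plane,
                      generate_fixation_hardware, PLATE_LENGTH)

__all__ = ["FractureSpec", "insert_fracture", "assemble_fixated_model",
           "SCENARIOS", "scenario_spec"]

SCENARIOS = ("human_body", "sheep_body", "sheep_diastema")


@dataclass(frozen=True)
class FractureSpec:
    """Transverse fracture definition.

    The capture radius limits gap selection to the vicinity of the plane
    origin so the infinite plane cannot also cut the contralateral body.
    """

    scenario: str
    plane_origin: np.ndarray
    plane_normal: np.ndarray
    gap_width: float = 1.5          # mm
    gap_material: str = "granulation"
    capture_radius: float = 40.0    # mm

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.gap_width <= 0:
            raise ValueError("gap_width must be > 0")
        n = np.asarray(self.plane_normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("plane_normal must be a unit vector")
        object.__setattr__(self, "plane_normal", n)
        object.__setattr__(self, "plane_origin",
                           np.asarray(self.plane_origin, dtype=float))

    @property
    def species(self) -> str:
        return "human" if self.scenario == "human_body" else "sheep"


def scenario_spec(params: AnatomyParams, scenario: str,
                  gap_width: float = 1.5) -> FractureSpec:
    """Preset FractureSpec for one of the three study scenarios."""
    if scenario.startswith("human") != (params.species == "human"):
        raise ValueError(f"scenario {scenario!r} inconsistent with species "
                         f"{params.species!r}")
    origin, normal, _ = fracture_plane(params, scenario)
    return FractureSpec(scenario=scenario, plane_origin=origin,
                        plane_normal=normal, gap_width=gap_width,
                        capture_radius=2.5 * params.body_width
                        + params.body_height)


def insert_fracture(mesh: TetMesh, spec: FractureSpec) -> TetMesh:
    """Reassign the elements inside the fracture slab to the gap material.

    The gap element set must be nonempty and must sever the load path:
    removing it has to split the mesh into (at least) two face-connected
    components, otherwise the plane did not span the full cross-section
    (usually the mesh is too coarse across the gap - refine locally).
    """
    if "fracture_gap" in mesh.element_sets:
        raise MeshError("mesh already contains a fracture gap")
    cent = mesh.centroids()
    dist = np.abs((cent - spec.plane_origin) @ spec.plane_normal)
    near = np.linalg.norm(cent - spec.plane_origin, axis=1) \
        <= spec.capture_radius
    gap = np.nonzero((dist <= spec.gap_width / 2.0) & near)[0]
    if len(gap) == 0:
        raise MeshError("empty fracture gap: no element centroid lies within "
                        f"{spec.gap_width / 2:.3g} mm of the plane")
    out = mesh.copy()
    out.material_labels[gap] = spec.gap_material
    out.element_sets["fracture_gap"] = gap

    # spanning check: the remaining elements must split into >= 2 components
    keep = np.setdiff1d(np.arange(mesh.n_elements), gap)
    adj = element_adjacency(out)
    sub = adj[keep][:, keep]
    n_comp, _ = connected_components(sub, directed=False)
    if n_comp < 2:
        raise MeshError("fracture gap does not span the cross-section; "
                        "removing it leaves the mesh connected")
    out.metadata["fracture"] = {
        "scenario": spec.scenario,
        "gap_width": spec.gap_width,
        "plane_origin": spec.plane_origin.tolist(),
        "plane_normal": spec.plane_normal.tolist(),
    }
    return out


def assemble_fixated_model(mesh: TetMesh, spec: FractureSpec,
                           hardware: TetMesh | None = None):
    """Fracture + two 4-hole miniplates with 2 screws per fragment.

    Returns ``(model, tie_pairs)``.  When ``hardware`` is given it must
    already contain the plates/screws for the same plane (the fracture
    is still inserted here); otherwise the hardware is generated.
    """
    if hardware is None:
        fractured = insert_fracture(mesh, spec)
        model = generate_fixation_hardware(fractured, spec.plane_origin,
                                           spec.plane_normal)
    else:
        fr = hardware.metadata.get("fracture")
        if "fracture_gap" not in hardware.element_sets:
            model = insert_fracture(hardware, spec)
        elif fr is None or not np.allclose(fr["plane_origin"],
                                           spec.plane_origin):
            raise MeshError("hardware mesh was built for a different "
                            "fracture plane")
        else:
            model = hardware
    for name in ("plate_top", "plate_bottom", "screws"):
        model.element_set(name)  # raises if missing
    ties = model.metadata.get("tie_pairs", [])
    if not ties:
        raise MeshError("fixated model has no tie pairs recorded")
    return model, ties
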