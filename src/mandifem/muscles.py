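"""PCSA-based muscle force model, clenching tasks, and load-case assembly.

Maximum muscle force follows F = A * K * PCSA with PCSA = muscle volume /
fiber length, the musculoskeletal constant K = 40 N/cm^2, and the fiber
activation ratio A in [0, 1] (A = 1 activates all fibers).  Muscle lines
of action are unit direction-cosine triples; the left side mirrors the
right by flipping the transverse (X) component.  A clenching task binds
per-muscle activations to the occlusal node sets whose vertical
displacement is suppressed: ICP constrains all molars and premolars, INC
all incisors, UNI the first-molar/second-premolar group of the working
side (right by default).  Condylar node sets are always fully restrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import yaml

from .mesh import TetMesh, MeshError

__all__ = [
    "K_MUSCLE",
    "MuscleGroup",
    "ClenchingTask",
    "LoadCase",
    "compute_pcsa",
    "muscle_force",
    "derive_lumped_activation",
    "load_muscle_registry",
    "muscle_groups",
    "clenching_task",
    "build_load_case",
    "TASK_NAMES",
]

K_MUSCLE = 40.0  # N/cm^2
TASK_NAMES = ("ICP", "INC", "UNI")
AXES = {"x": 0, "y": 1, "z": 2}


def compute_pcsa(volume: float, fiber_length: float) -> float:
    """Physiological cross-sectional area (cm^2) = volume / fiber length."""
    if volume <= 0 or fiber_length <= 0:
        raise ValueError("muscle volume and fiber length must be positive")
    return volume / fiber_length


def muscle_force(activation: float, k: float, pcsa: float) -> float:
    """Muscle force F = A * K * PCSA in newtons."""
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation {activation} outside [0, 1]")
    if k <= 0 or pcsa <= 0:
        raise ValueError("K and PCSA must be positive")
    return activation * k * pcsa


def derive_lumped_activation(activations) -> float:
    """Lumped activation of a merged muscle group: arithmetic mean.

    Used for the sheep temporalis, modelled as a whole because its
    anterior/medial/posterior parts cannot be distinguished reliably.
    """
    acts = list(activations)
    if not acts:
        raise ValueError("need at least one activation to lump")
    for a in acts:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"activation {a} outside [0, 1]")
    return float(np.mean(acts))


@dataclass(frozen=True)
class MuscleGroup:
    """One side of a jaw-closing muscle with its line of action."""

    name: str
    side: str                      # "left" | "right"
    attachment_set: str
    direction: np.ndarray          # unit direction cosines, this side
    max_force: float               # N
    volume: float | None = None    # cm^3
    fiber_length: float | None = None  # cm
    pcsa: float | None = None      # cm^2

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", d)
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if not 0.98 <= float(np.linalg.norm(d)) <= 1.02:
            raise ValueError(f"{self.name}/{self.side}: direction cosines "
                             f"not unit within rounding")
        if self.max_force < 0:
            raise ValueError("max_force must be >= 0")


@dataclass(frozen=True)
class ClenchingTask:
    name: str
    activations: Dict[Tuple[str, str], float]
    occlusal_sets: Tuple[str, ...]
    working_side: str = "none"

    def __post_init__(self):
        if not self.occlusal_sets:
            raise ValueError("a clenching task needs occlusal constraints")
        for a in self.activations.values():
            if not 0.0 <= a <= 1.0:
                raise ValueError("activations must lie in [0, 1]")


@dataclass
class LoadCase:
    """Nodal forces (N) and single-axis displacement constraints."""

    nodal_forces: Dict[int, np.ndarray] = field(default_factory=dict)
    fixed_dofs: List[Tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        fixed = set(self.fixed_dofs)
        for node, f in self.nodal_forces.items():
            for ax in range(3):
                if f[ax] != 0.0 and (node, ax) in fixed:
                    raise ValueError(f"node {node} has both a nonzero force "
                                     f"and a fixed DOF on axis {ax}")

    def total_force(self) -> np.ndarray:
        if not self.nodal_forces:
            return np.zeros(3)
        return np.sum(list(self.nodal_forces.values()), axis=0)


# ---------------------------------------------------------------------------
# registry


def load_muscle_registry() -> dict:
    """Muscle table shipped with the package (both species), parsed once."""
    text = resources.files("mandifem.data").joinpath(
        "muscle_registry.yaml").read_text()
    return yaml.safe_load(text)


def muscle_groups(species: str) -> List[MuscleGroup]:
    """Left+right MuscleGroup list for a species, X flipped on the left."""
    reg = load_muscle_registry()
    if species not in reg:
        raise ValueError(f"unknown species {species!r}")
    groups = []
    for row in reg[species]:
        d_right = np.asarray(row["direction"], dtype=float)
        for side, d in (("right", d_right),
                        ("left", d_right * np.array([-1.0, 1.0, 1.0]))):
            groups.append(MuscleGroup(
                name=row["name"], side=side,
                attachment_set=f"{row['set']}_{'R' if side == 'right' else 'L'}",
                direction=d, max_force=float(row["max_force"]),
                volume=row.get("volume"), fiber_length=row.get("fiber_length"),
                pcsa=row.get("pcsa")))
    return groups


def _occlusal_sets(task: str, working_side: str) -> Tuple[str, ...]:
    if task == "ICP":
        return ("occlusal_molar_L", "occlusal_molar_R",
                "occlusal_premolar_L", "occlusal_premolar_R")
    if task == "INC":
        return ("occlusal_incisor",)
    if task == "UNI":
        return (f"occlusal_uni_{'R' if working_side == 'right' else 'L'}",)
    raise ValueError(f"unknown clenching task {task!r}")


def clenching_task(name: str, species: str,
                   working_side: str = "right") -> ClenchingTask:
    """Task preset with the registry's activation pattern for a species.

    For UNI the default working side is the right body (mirrored option
    available); ICP/INC are bilateral (working_side = "none").
    """
    if name not in TASK_NAMES:
        raise ValueError(f"unknown clenching task {name!r}")
    reg = load_muscle_registry()
    acts: Dict[Tuple[str, str], float] = {}
    for row in reg[species]:
        a_right, a_left = row["activation"][name]
        if name == "UNI" and working_side == "left":
            a_right, a_left = a_left, a_right
        acts[(row["name"], "right")] = float(a_right)
        acts[(row["name"], "left")] = float(a_left)
    ws = working_side if name == "UNI" else "none"
    return ClenchingTask(name=name, activations=acts,
                         occlusal_sets=_occlusal_sets(name, working_side),
                         working_side=ws)


def build_load_case(mesh: TetMesh, muscles: List[MuscleGroup],
                    task: ClenchingTask) -> LoadCase:
    """Assemble nodal forces and boundary conditions for one clenching task.

    Each muscle's total force A * F_max acts along its side-specific
    direction cosines, shared equally over the nodes of its attachment
    patch.  All three translations are fixed on both condylar node sets
    (solid elements carry no rotational DOFs, so clamping the patch also
    suppresses its rigid rotation) and the vertical translation on every
    node of the task's occlusal sets.
    """
    case = LoadCase()
    for m in muscles:
        try:
            a = task.activations[(m.name, m.side)]
        except KeyError:
            raise ValueError(f"no activation for muscle {m.name!r} "
                             f"({m.side}) in task {task.name}") from None
        patch = mesh.node_set(m.attachment_set)
        f_total = a * m.max_force * m.direction
        share = f_total / len(patch)
        for n in patch:
            prev = case.nodal_forces.get(int(n))
            case.nodal_forces[int(n)] = share.copy() if prev is None \
                else prev + share

    for name in ("condyle_L", "condyle_R"):
        for n in mesh.node_set(name):
            case.fixed_dofs.extend(((int(n), 0), (int(n), 1), (int(n), 2)))
    for name in task.occlusal_sets:
        for n in mesh.node_set(name):
            case.fixed_dofs.append((int(n), 2))
    # deterministic, duplicate-free constraint list
    case.fixed_dofs = sorted(set(case.fixed_dofs))
    case.validate()
    return case
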