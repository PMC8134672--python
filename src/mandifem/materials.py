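"""Isotropic linear-elastic material cards and the default registries.

All moduli in MPa (N/mm^2).  Bone tissues and the fracture-gap
granulation tissue use nu = 0.30; the Ti-6Al-4V osteosynthesis alloy
uses nu = 0.34 with an 880 MPa yield strength kept as a reporting
threshold for implant failure prediction (the analysis itself stays
linear elastic).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialCard:
    name: str
    youngs_modulus: float  # MPa
    poissons_ratio: float
    yield_strength: float | None = None  # MPa, reporting threshold only

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError(f"{self.name}: Young's modulus must be > 0")
        if not -1.0 < self.poissons_ratio < 0.5:
            raise ValueError(f"{self.name}: Poisson's ratio out of (-1, 0.5)")


TITANIUM_YIELD_MPA = 880.0

#: Default card sets per species.  Cortical stiffness differs between the
#: human (15,000 MPa) and sheep (15,750 MPa) models; everything else is
#: shared.
HUMAN_MATERIALS = {
    "cortical": MaterialCard("cortical", 15_000.0, 0.30),
    "trabecular": MaterialCard("trabecular", 300.0, 0.30),
    "granulation": MaterialCard("granulation", 1.0, 0.30),
    "titanium": MaterialCard("titanium", 110_000.0, 0.34, TITANIUM_YIELD_MPA),
}

SHEEP_MATERIALS = {
    **HUMAN_MATERIALS,
    "cortical": MaterialCard("cortical", 15_750.0, 0.30),
}


def material_registry(species: str) -> dict:
    if species == "human":
        return dict(HUMAN_MATERIALS)
    if species == "sheep":
        return dict(SHEEP_MATERIALS)
    raise ValueError(f"unknown species {species!r}")
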