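"""Parametric surrogate mandible geometries.

The generator replaces subject-specific CT reconstructions with an
idealized mandible built by constructive mapping of structured hex grids
(then split into conforming tetrahedra): a horseshoe-shaped body swept
along a circular arc, carrying at each posterior end a vertical ramus
whose top profile rises into a condylar prominence (posterior) and a
coronoid prominence (anterior) separated by a sigmoid notch.  A cortical
shell of prescribed thickness encloses a trabecular core.  The sheep
variant has an elongated body with a toothless diastema span between the
incisor and premolar regions.

Coordinates: X transverse (+X = right), Y antero-posterior (+Y = chin),
Z vertical (occlusal axis).  XY is the transverse plane, XZ coronal,
YZ sagittal.  All lengths in millimetres.

Anatomical regions are laid out in a normalized per-side coordinate
``t = |2 s - 1|`` (0 at the chin, 1 at the posterior ramus end, ``s``
the normalized arc position).  Grid breakpoints are snapped to every
region boundary and to the cortical interfaces, so meshes at different
target edge lengths discretize the identical geometry - a prerequisite
for a clean mesh-convergence study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .mesh import TetMesh, MeshError, _HEX_TO_TETS

__all__ = [
    "AnatomyParams",
    "HUMAN_DEFAULTS",
    "SHEEP_DEFAULTS",
    "default_params",
    "generate_mandible",
    "generate_fixation_hardware",
    "fracture_plane",
    "PLATE_LENGTH",
    "SCREW_OFFSETS",
]

#: fraction of the per-side coordinate t occupied by the ramus footprint
T_RAMUS = 0.78
#: ramus top-profile notch (fraction of ramus height) between the
#: coronoid (anterior) and condylar (posterior) prominences
NOTCH_DEPTH = 0.35

# fixation hardware geometry (mm): 4-hole miniplate of the 2.0 system,
# 1 mm thick, and square-section monocortical screws 7 mm long (1 mm of
# which crosses the plate).  The 2 mm screw "diameter" is modelled as a
# 2 x 2 mm square section (no thread, no plate-hole geometry).
PLATE_LENGTH = 24.0
PLATE_HEIGHT = 4.0
PLATE_THICKNESS = 1.0
SCREW_OFFSETS = (-10.5, -4.5, 4.5, 10.5)
SCREW_SIDE = 2.0
SCREW_LENGTH = 7.0
PLATE_Z_FRACTIONS = (0.62, 0.34)  # top / bottom plate centre heights


@dataclass(frozen=True)
class AnatomyParams:
    """Geometric parameters of the surrogate mandible (all mm)."""

    species: str
    body_length: float          # arc length of the body centreline
    body_height: float
    body_width: float
    arch_radius: float          # centreline arc radius
    ramus_height: float
    diastema_length: float      # sheep only; 0 for human
    cortical_thickness: float
    target_edge_length: float
    seed: int = 0
    jitter: float = 0.0         # interior-node jitter, fraction of edge length
    refine_band: Tuple[float, float, float] | None = None  # (s_lo, s_hi, h)
    snap_s: Tuple[float, ...] | None = None  # extra grid breakpoints in s

    def __post_init__(self):
        if self.species not in ("human", "sheep"):
            raise ValueError(f"unknown species {self.species!r}")
        for name in ("body_length", "body_height", "body_width",
                     "arch_radius", "ramus_height", "cortical_thickness",
                     "target_edge_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.species == "human" and self.diastema_length != 0:
            raise ValueError("human mandible has no diastema "
                             "(diastema_length must be 0)")
        if self.species == "sheep" and self.diastema_length <= 0:
            raise ValueError("sheep mandible requires diastema_length > 0")
        if self.cortical_thickness >= self.body_width / 2:
            raise ValueError("cortical_thickness must be < body_width/2")
        tr = self.tooth_ranges()
        if tr["molar"][1] > T_RAMUS + 1e-9:
            raise ValueError("diastema_length too large: tooth row would "
                             "extend into the ramus footprint")

    # -- derived layout ----------------------------------------------------
    def arc_half_angle(self) -> float:
        return self.body_length / (2.0 * self.arch_radius)

    def tooth_ranges(self) -> dict:
        """Per-side t-ranges of the occlusal groups (and diastema)."""
        if self.species == "human":
            return {
                "incisor": (0.0, 0.14),
                "premolar": (0.38, 0.56),
                "molar": (0.56, 0.74),
                "uni": (0.47, 0.62),
            }
        t_d0 = 0.10
        t_d1 = t_d0 + self.diastema_length / (self.body_length / 2.0)
        pm1 = t_d1 + 0.01
        pm_mo = pm1 + 0.11
        return {
            "incisor": (0.0, 0.08),
            "diastema": (t_d0, t_d1),
            "premolar": (pm1, pm_mo),
            "molar": (pm_mo, pm_mo + 0.11),
            "uni": (pm_mo - 0.04, pm_mo + 0.04),
        }


HUMAN_DEFAULTS = AnatomyParams(
    species="human", body_length=100.0, body_height=25.0, body_width=14.0,
    arch_radius=45.0, ramus_height=40.0, diastema_length=0.0,
    cortical_thickness=2.8, target_edge_length=4.0)

#: Sheep defaults: body more than twice as long as the human surrogate and
#: the whole mandible more than three times its volume, the two printed
#: geometric constraints; remaining dimensions are generator choices.
SHEEP_DEFAULTS = AnatomyParams(
    species="sheep", body_length=200.0, body_height=34.0, body_width=22.0,
    arch_radius=110.0, ramus_height=48.0, diastema_length=45.0,
    cortical_thickness=3.2, target_edge_length=5.0)

#: Cross-section reduction of the toothless diastema span (the slender
#: waist of the sheep mandible): width and height scale factors, with a
#: smooth cosine ramp of this t-half-width at both ends.  The reduced
#: section is what concentrates strain in the diastema relative to the
#: tooth-bearing body.
DIASTEMA_WIDTH_SCALE = 0.60
DIASTEMA_HEIGHT_SCALE = 0.65
DIASTEMA_RAMP = 0.06


def _diastema_scales(t, t0, t1):
    """Smooth (width, height) scale factors across the diastema span."""
    t = np.asarray(t, dtype=float)
    ramp = np.clip((t - t0) / DIASTEMA_RAMP, 0.0, 1.0) \
        * np.clip((t1 - t) / DIASTEMA_RAMP, 0.0, 1.0)
    ramp = np.clip(ramp, 0.0, 1.0)
    blend = 0.5 - 0.5 * np.cos(np.pi * ramp)
    w = 1.0 + (DIASTEMA_WIDTH_SCALE - 1.0) * blend
    h = 1.0 + (DIASTEMA_HEIGHT_SCALE - 1.0) * blend
    return w, h


def default_params(species: str) -> AnatomyParams:
    if species == "human":
        return HUMAN_DEFAULTS
    if species == "sheep":
        return SHEEP_DEFAULTS
    raise ValueError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# grid helpers


def _fill_breaks(features, base_step, band=None):
    """Uniformly subdivide between sorted feature breakpoints.

    ``band = (lo, hi, step)`` overrides the step inside a refinement band.
    """
    feats = sorted(set(float(f) for f in features))
    out = [feats[0]]
    eps = 1e-12
    for a, b in zip(feats[:-1], feats[1:]):
        if b - a < 1e-9:
            continue
        step = base_step
        if band is not None and a >= band[0] - eps and b <= band[1] + eps:
            step = band[2]
        n = max(1, int(round((b - a) / step)))
        out.extend(np.linspace(a, b, n + 1)[1:].tolist())
    return np.asarray(out)


def _ramus_profile(s_local: np.ndarray | float):
    """Top-edge height fraction along the ramus footprint.

    ``s_local`` runs 0 (anterior, coronoid) to 1 (posterior, condyle); the
    Gaussian notch between the prominences dips to 1 - NOTCH_DEPTH.
    """
    return 1.0 - NOTCH_DEPTH * np.exp(-(((np.asarray(s_local) - 0.55) / 0.16) ** 2))


# ---------------------------------------------------------------------------
# main generator


def generate_mandible(params: AnatomyParams) -> TetMesh:
    """Build the labelled surrogate mandible mesh for one species.

    Returns a watertight linear-tet mesh with a one-cell cortical shell
    ("cortical") enclosing a trabecular core ("trabecular"), the condylar,
    occlusal and muscle-attachment node sets, and the region element sets
    used downstream ("mandibular_body", plus "diastema_region" and the
    per-side "ramus_L/R").  Identical parameters (including seed)
    reproduce the identical mesh.
    """
    p = params
    L, W, H = p.body_length, p.body_width, p.body_height
    Rc, Rh, tc = p.arch_radius, p.ramus_height, p.cortical_thickness
    h = p.target_edge_length
    phi = p.arc_half_angle()
    ranges = p.tooth_ranges()

    # --- s breakpoints: region boundaries, cortical end bands, ramus bands
    s_feats = {0.0, 0.5, 1.0, tc / L, 1.0 - tc / L}
    s_b = (1.0 - T_RAMUS) / 2.0          # ramus footprint boundary (left side)
    for sb in (s_b, 1.0 - s_b):
        s_feats.add(sb)
    # cortical band at the anterior ramus face
    s_feats.update({s_b + tc / L, 1.0 - s_b - tc / L})
    for lo, hi in ranges.values():
        s_feats.update({0.5 - lo / 2, 0.5 - hi / 2, 0.5 + lo / 2, 0.5 + hi / 2})
    if p.snap_s:
        s_feats.update(float(s) for s in p.snap_s)
    s_feats = {s for s in s_feats if -1e-9 <= s <= 1 + 1e-9}
    band = None
    if p.refine_band is not None:
        lo, hi, hf = p.refine_band
        s_feats.update((lo, hi))
        band = (lo, hi, hf / L)
    s_breaks = _fill_breaks(s_feats, h / L, band)

    # --- u breakpoints (transverse, [-1, 1]); cortical at |u| > u_c
    u_c = 1.0 - 2.0 * tc / W
    n_cort = max(1, int(round(tc / h)))
    n_core = max(2, int(round(2 * u_c * (W / 2) / h)))
    u_breaks = np.concatenate([
        np.linspace(-1.0, -u_c, n_cort + 1),
        np.linspace(-u_c, u_c, n_core + 1)[1:],
        np.linspace(u_c, 1.0, n_cort + 1)[1:],
    ])

    # --- v breakpoints (vertical, [0, 1]); cortical below v_c0 / above v_c1
    v_c0, v_c1 = tc / H, 1.0 - tc / H
    n_mid = max(2, int(round((v_c1 - v_c0) * H / h)))
    v_breaks = np.concatenate([
        np.linspace(0.0, v_c0, n_cort + 1),
        np.linspace(v_c0, v_c1, n_mid + 1)[1:],
        np.linspace(v_c1, 1.0, n_cort + 1)[1:],
    ])

    # --- ramus extrusion fractions; cortical cap above g_c
    g_c = 1.0 - tc / Rh
    n_ram = max(3, int(round(g_c * Rh / h)))
    g_breaks = np.concatenate([
        np.linspace(0.0, g_c, n_ram + 1),
        np.linspace(g_c, 1.0, n_cort + 1)[1:],
    ])

    ns, nu, nv = len(s_breaks) - 1, len(u_breaks) - 1, len(v_breaks) - 1
    ng = len(g_breaks) - 1

    theta = (2.0 * s_breaks - 1.0) * phi

    # --- body nodes
    node_id = {}
    coords = []

    def add_node(key, xyz):
        node_id[key] = len(coords)
        coords.append(xyz)

    # chin at -Y (anterior), posterior ends toward +Y, +X = right side,
    # matching the sign convention of the muscle direction-cosine tables
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    t_node_all = np.abs(2.0 * s_breaks - 1.0)
    if "diastema" in ranges:
        w_sc, h_sc = _diastema_scales(t_node_all, *ranges["diastema"])
    else:
        w_sc = h_sc = np.ones_like(s_breaks)
    for i in range(ns + 1):
        for j in range(nu + 1):
            rho = Rc + u_breaks[j] * (W / 2.0) * w_sc[i]
            for k in range(nv + 1):
                add_node(("b", i, j, k),
                         (rho * sin_t[i], -rho * cos_t[i],
                          v_breaks[k] * H * h_sc[i]))

    # --- ramus nodes (shared layer 0 with body top)
    i_left = int(np.argmin(np.abs(s_breaks - s_b)))
    i_right = int(np.argmin(np.abs(s_breaks - (1.0 - s_b))))

    def s_local_of(i):
        s = s_breaks[i]
        return (1.0 - s / s_breaks[i_left]) if s <= s_breaks[i_left] + 1e-12 \
            else (s - s_breaks[i_right]) / (1.0 - s_breaks[i_right])

    ramus_cols = {"L": list(range(0, i_left + 1)),
                  "R": list(range(i_right, ns + 1))}
    for side, cols in ramus_cols.items():
        for i in cols:
            prof = float(_ramus_profile(s_local_of(i)))
            for j in range(nu + 1):
                rho = Rc + u_breaks[j] * W / 2.0
                x, y = rho * sin_t[i], -rho * cos_t[i]
                for g in range(1, ng + 1):
                    z = H + g_breaks[g] * Rh * prof
                    add_node(("r", i, j, g), (x, y, z))

    coords = np.asarray(coords, dtype=float)

    # optional seeded jitter of strictly interior body nodes; the
    # amplitude scales with the smallest cell dimension so thin cortical
    # layers cannot invert
    if p.jitter > 0:
        rng = np.random.default_rng(p.seed)
        amp = p.jitter * min(np.diff(s_breaks).min() * L,
                             np.diff(u_breaks).min() * W / 2.0,
                             np.diff(v_breaks).min() * H)
        for i in range(1, ns):
            if i <= i_left or i >= i_right:
                continue
            for j in range(1, nu):
                for k in range(1, nv):
                    coords[node_id[("b", i, j, k)]] += rng.uniform(-amp, amp, 3)

    # --- elements
    elements, labels, cell_tags = [], [], []
    s_mid = 0.5 * (s_breaks[:-1] + s_breaks[1:])
    u_mid = 0.5 * (u_breaks[:-1] + u_breaks[1:])
    v_mid = 0.5 * (v_breaks[:-1] + v_breaks[1:])
    g_mid = 0.5 * (g_breaks[:-1] + g_breaks[1:])
    t_mid = np.abs(2.0 * s_mid - 1.0)

    def emit_cell(nid8, label, tag):
        # the swept map with the chin at -Y is left-handed in (s, u, v);
        # reversing the s-axis of each cell restores positive volumes
        nid8 = [nid8[1], nid8[0], nid8[3], nid8[2],
                nid8[5], nid8[4], nid8[7], nid8[6]]
        for t in _HEX_TO_TETS:
            elements.append([nid8[t[0]], nid8[t[1]], nid8[t[2]], nid8[t[3]]])
            labels.append(label)
            cell_tags.append(tag)

    for i in range(ns):
        in_end_band = s_mid[i] < tc / L or s_mid[i] > 1.0 - tc / L
        for j in range(nu):
            cort_u = abs(u_mid[j]) > u_c
            for k in range(nv):
                cortical = cort_u or v_mid[k] < v_c0 or v_mid[k] > v_c1 \
                    or in_end_band
                nid8 = [node_id[("b", i, j, k)], node_id[("b", i + 1, j, k)],
                        node_id[("b", i + 1, j + 1, k)], node_id[("b", i, j + 1, k)],
                        node_id[("b", i, j, k + 1)], node_id[("b", i + 1, j, k + 1)],
                        node_id[("b", i + 1, j + 1, k + 1)], node_id[("b", i, j + 1, k + 1)]]
                emit_cell(nid8, "cortical" if cortical else "trabecular",
                          ("body", i))

    def rnode(i, j, g):
        return node_id[("b", i, j, nv)] if g == 0 else node_id[("r", i, j, g)]

    for side, cols in ramus_cols.items():
        sb_lo, sb_hi = (0.0, s_breaks[i_left]) if side == "L" \
            else (s_breaks[i_right], 1.0)
        for i in cols[:-1]:
            anterior_band = (s_breaks[i_left] - s_mid[i] < tc / L) if side == "L" \
                else (s_mid[i] - s_breaks[i_right] < tc / L)
            in_end_band = s_mid[i] < tc / L or s_mid[i] > 1.0 - tc / L
            for j in range(nu):
                cort_u = abs(u_mid[j]) > u_c
                for g in range(ng):
                    cortical = cort_u or g_mid[g] > g_c or anterior_band \
                        or in_end_band
                    nid8 = [rnode(i, j, g), rnode(i + 1, j, g),
                            rnode(i + 1, j + 1, g), rnode(i, j + 1, g),
                            rnode(i, j, g + 1), rnode(i + 1, j, g + 1),
                            rnode(i + 1, j + 1, g + 1), rnode(i, j + 1, g + 1)]
                    emit_cell(nid8, "cortical" if cortical else "trabecular",
                              ("ramus" + side, i))

    elements = np.asarray(elements, dtype=np.int64)
    labels = np.asarray(labels, dtype=object)

    # --- element sets
    elem_sets = {}
    tags = cell_tags
    body_ids = [e for e, tg in enumerate(tags) if tg[0] == "body"]
    in_diastema = np.zeros(ns, dtype=bool)
    if "diastema" in ranges:
        lo, hi = ranges["diastema"]
        in_diastema = (t_mid > lo - 1e-9) & (t_mid < hi + 1e-9)
    body_mask_cols = t_mid < T_RAMUS - 1e-9
    elem_sets["mandibular_body"] = np.asarray(
        [e for e in body_ids
         if body_mask_cols[tags[e][1]] and not in_diastema[tags[e][1]]],
        dtype=np.int64)
    if "diastema" in ranges:
        elem_sets["diastema_region"] = np.asarray(
            [e for e in body_ids if in_diastema[tags[e][1]]], dtype=np.int64)
    for side in ("L", "R"):
        elem_sets["ramus_" + side] = np.asarray(
            [e for e, tg in enumerate(tags) if tg[0] == "ramus" + side],
            dtype=np.int64)

    # --- node sets
    node_sets = {}

    def nset(name, ids):
        arr = np.unique(np.asarray(sorted(ids), dtype=np.int64))
        if len(arr) == 0:
            raise MeshError(f"node set {name!r} came out empty; degenerate "
                            f"anatomy parameters (edge length too coarse?)")
        node_sets[name] = arr

    # occlusal groups: top body surface nodes outside the ramus footprint
    t_node = np.abs(2.0 * s_breaks - 1.0)
    eps = 1e-9
    for group in ("incisor", "premolar", "molar", "uni"):
        lo, hi = ranges[group]
        cols = [i for i in range(ns + 1)
                if lo - eps <= t_node[i] <= hi + eps and t_node[i] < T_RAMUS]
        ids_L = [node_id[("b", i, j, nv)] for i in cols if s_breaks[i] <= 0.5
                 for j in range(nu + 1)]
        ids_R = [node_id[("b", i, j, nv)] for i in cols if s_breaks[i] >= 0.5
                 for j in range(nu + 1)]
        if group == "incisor":
            nset("occlusal_incisor", ids_L + ids_R)
        elif group == "uni":
            nset("occlusal_uni_L", ids_L)
            nset("occlusal_uni_R", ids_R)
        else:
            nset(f"occlusal_{group}_L", ids_L)
            nset(f"occlusal_{group}_R", ids_R)

    # ramus surface patches, classified by (s_local, u, extrusion fraction).
    # The temporalis inserts on the coronoid (upper anterior ramus); the
    # human model splits it into posterior/medial/anterior sub-patches by
    # stacking the available extrusion levels above 0.5 bottom-to-top,
    # guaranteeing each sub-patch is nonempty at any resolution.
    temp_levels = sorted(g for g in g_breaks[1:] if g >= 0.5 - 1e-9)
    if p.species == "human":
        thirds = np.array_split(np.asarray(temp_levels), 3)
        temporalis_layers = {name: set(np.round(part, 12))
                             for name, part in zip(("PT", "MT", "AT"), thirds)}
    else:
        temporalis_layers = {"TEMP": set(np.round(temp_levels, 12))}
    for side, cols in ramus_cols.items():
        buccal, lingual = nu, 0
        condyle, coronoid = [], []
        sm, dm, mpt, lpt = [], [], [], []
        temp = {name: [] for name in temporalis_layers}
        for i in cols:
            sl = s_local_of(i)
            for g in range(1, ng + 1):
                gf = g_breaks[g]
                top = g == ng
                for j in range(nu + 1):
                    nid = node_id[("r", i, j, g)]
                    if top and sl >= 0.75:
                        condyle.append(nid)
                    if top and sl <= 0.35:
                        coronoid.append(nid)
                    on_buccal, on_lingual = j == buccal, j == lingual
                    if on_buccal and gf < 0.5:
                        sm.append(nid)
                    if on_buccal and 0.5 <= gf < 0.85 and sl >= 0.40:
                        dm.append(nid)
                    if on_lingual and gf < 0.45 and sl >= 0.45:
                        mpt.append(nid)
                    if on_lingual and 0.45 <= gf < 0.80 and sl >= 0.70:
                        lpt.append(nid)
                    # temporalis inserts on the coronoid; patches are
                    # stacked by extrusion level and stay disjoint from
                    # the masseter (below 0.5) and condylar sets
                    if sl <= 0.35 and (on_buccal or on_lingual or top):
                        gf_key = round(gf, 12)
                        for name, levels in temporalis_layers.items():
                            if gf_key in levels:
                                temp[name].append(nid)
        nset(f"condyle_{side}", condyle)
        nset(f"coronoid_{side}", coronoid)
        nset(f"SM_{side}", sm)
        nset(f"DM_{side}", dm)
        nset(f"MPt_{side}", mpt)
        nset(f"LPt_{side}", lpt)
        for name, ids in temp.items():
            nset(f"{name}_{side}", ids)

    mesh = TetMesh(
        nodes=coords, elements=elements, order="linear",
        node_sets=node_sets, element_sets=elem_sets,
        material_labels=labels,
        metadata={
            "anatomy": {
                "species": p.species, "body_length": L, "body_height": H,
                "body_width": W, "arch_radius": Rc, "ramus_height": Rh,
                "diastema_length": p.diastema_length,
                "cortical_thickness": tc, "target_edge_length": h,
                "seed": p.seed,
                "arc_half_angle": phi,
                "diastema_range": list(ranges["diastema"])
                if "diastema" in ranges else None,
            },
            "warnings": [],
        })
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# fracture plane presets and fixation hardware


def fracture_plane(params: AnatomyParams, scenario: str):
    """Preset transverse fracture plane (origin, unit normal) for a scenario.

    ``human_body`` / ``sheep_body``: between the last premolar and the
    first molar of the left body; ``sheep_diastema``: at the distal
    (posterior) end of the diastema.  The normal is the local centreline
    tangent, i.e. the plane cuts the body transversely.
    """
    ranges = params.tooth_ranges()
    if scenario in ("human_body", "sheep_body"):
        t_f = ranges["premolar"][1]
    elif scenario == "sheep_diastema":
        t_f = ranges["diastema"][1]
    else:
        raise ValueError(f"unknown fracture scenario {scenario!r}")
    s_f = 0.5 - t_f / 2.0  # left side
    phi = params.arc_half_angle()
    th = (2.0 * s_f - 1.0) * phi
    origin = np.array([params.arch_radius * math.sin(th),
                       -params.arch_radius * math.cos(th),
                       params.body_height / 2.0])
    normal = np.array([math.cos(th), math.sin(th), 0.0])
    return origin, normal, s_f


def generate_fixation_hardware(mesh: TetMesh, plane_origin, plane_normal,
                               tie_tolerance: float | None = None) -> TetMesh:
    """Append two miniplates and eight screws bridging a fracture plane.

    The plates are flush-bent onto the buccal surface (generated in the
    same swept-arc coordinates as the bone, so they follow its curvature);
    each plate carries two screws per fracture side.  Screw solids are
    7 mm long: 1 mm crossing the plate and 6 mm into the bone.  Tie pairs
    (slave hardware node -> nearest master node, with distance) are
    recorded in ``metadata["tie_pairs"]``: screw ends onto the plate and
    the monocortical screw shaft onto cortical-bone nodes only.
    """
    meta = mesh.metadata.get("anatomy")
    if meta is None:
        raise MeshError("mesh lacks anatomy metadata; hardware placement "
                        "requires a generated mandible")
    origin = np.asarray(plane_origin, dtype=float)
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    if np.any(origin < lo - 1.0) or np.any(origin > hi + 1.0):
        raise MeshError("fracture plane origin lies outside the mesh "
                        "bounding box")
    W, H = meta["body_width"], meta["body_height"]
    Rc, tc = meta["arch_radius"], meta["cortical_thickness"]
    psi0 = math.atan2(origin[0], -origin[1])
    # local cross-section at the plating site (the diastema is tapered)
    w_loc, h_loc = 1.0, 1.0
    if meta.get("diastema_range"):
        phi = meta.get("arc_half_angle",
                       meta["body_length"] / (2.0 * Rc))
        t_here = abs(psi0) / phi
        ws, hs = _diastema_scales(t_here, *meta["diastema_range"])
        w_loc, h_loc = float(ws), float(hs)
    rho_b = Rc + (W / 2.0) * w_loc
    H = H * h_loc
    if tie_tolerance is None:
        tie_tolerance = 1.6 * meta["target_edge_length"]

    out = mesh.copy()
    warnings = out.metadata.setdefault("warnings", [])
    if SCREW_LENGTH - PLATE_THICKNESS > W:
        warnings.append("screw length exceeds local bone depth")

    nodes = [out.nodes]
    elements = [out.elements]
    labels = [out.material_labels]
    n_base = out.n_nodes
    new_sets = {"plate_top": [], "plate_bottom": [], "screws": []}
    tie_pairs = list(out.metadata.get("tie_pairs", []))

    cort_elems = np.nonzero(out.material_labels == "cortical")[0]
    cort_nodes = np.unique(out.elements[cort_elems, :4].ravel())
    cort_xyz = out.nodes[cort_nodes]

    def swept(a, d, z):
        psi = psi0 + a / rho_b
        rho = rho_b + d
        return (rho * math.sin(psi), -rho * math.cos(psi), z)

    def add_block(a_breaks, d_breaks, z_breaks, label):
        """Structured block in (arc offset, depth, height) coordinates."""
        na, nd, nz = len(a_breaks) - 1, len(d_breaks) - 1, len(z_breaks) - 1
        offset = n_base + sum(len(n) for n in nodes[1:])
        blk = np.empty(((na + 1) * (nd + 1) * (nz + 1), 3))
        idx = 0
        for ia in range(na + 1):
            for jd in range(nd + 1):
                for kz in range(nz + 1):
                    blk[idx] = swept(a_breaks[ia], d_breaks[jd], z_breaks[kz])
                    idx += 1

        def nid(i, j, k):
            return offset + (i * (nd + 1) + j) * (nz + 1) + k

        tets = []
        for i in range(na):
            for j in range(nd):
                for k in range(nz):
                    # a-axis reversed: the swept map is left-handed in
                    # (a, d, z) with the chin at -Y
                    v = [nid(i + 1, j, k), nid(i, j, k), nid(i, j + 1, k),
                         nid(i + 1, j + 1, k), nid(i + 1, j, k + 1),
                         nid(i, j, k + 1), nid(i, j + 1, k + 1),
                         nid(i + 1, j + 1, k + 1)]
                    for t in _HEX_TO_TETS:
                        tets.append([v[t[0]], v[t[1]], v[t[2]], v[t[3]]])
        e_offset = sum(len(e) for e in elements)
        nodes.append(blk)
        elements.append(np.asarray(tets, dtype=np.int64))
        labels.append(np.full(len(tets), "titanium", dtype=object))
        new_sets[label].extend(range(e_offset, e_offset + len(tets)))
        return offset, blk

    # plates
    a_pl = sorted(set(np.linspace(-PLATE_LENGTH / 2, PLATE_LENGTH / 2, 17))
                  | set(SCREW_OFFSETS))
    for z_frac, label in zip(PLATE_Z_FRACTIONS, ("plate_top", "plate_bottom")):
        zc = z_frac * H
        z_breaks = [zc - PLATE_HEIGHT / 2, zc, zc + PLATE_HEIGHT / 2]
        add_block(np.asarray(a_pl), np.asarray([0.0, PLATE_THICKNESS]),
                  np.asarray(z_breaks), label)

    # screws: depth breakpoints put nodes at the bone surface (d = 0) and
    # the plate outer face (d = +1); the shaft reaches 6 mm into the bone
    d_scr = np.asarray([-(SCREW_LENGTH - PLATE_THICKNESS), -4.0, -2.0, 0.0,
                        PLATE_THICKNESS])
    # the first two appended blocks are the plates
    plate_offsets = (n_base, n_base + len(nodes[1]))
    for bi, z_frac in enumerate(PLATE_Z_FRACTIONS):
        zc = z_frac * H
        p_off, p_blk = plate_offsets[bi], nodes[1 + bi]
        for a_s in SCREW_OFFSETS:
            a_breaks = np.asarray([a_s - SCREW_SIDE / 2, a_s, a_s + SCREW_SIDE / 2])
            z_breaks = np.asarray([zc - SCREW_SIDE / 2, zc, zc + SCREW_SIDE / 2])
            s_off, s_blk = add_block(a_breaks, d_scr, z_breaks, "screws")
            nd, nz = len(d_scr) - 1, len(z_breaks) - 1
            for idx, xyz in enumerate(s_blk):
                jd = (idx // (nz + 1)) % (nd + 1)
                d_val = d_scr[jd]
                nid = s_off + idx
                if d_val >= -1e-9:  # inside / against the plate
                    dist = np.linalg.norm(p_blk - xyz, axis=1)
                    m = int(np.argmin(dist))
                    tie_pairs.append((nid, p_off + m, float(dist[m])))
                elif -d_val <= max(tc, 2.0) + 1e-9:  # monocortical engagement
                    dist = np.linalg.norm(cort_xyz - xyz, axis=1)
                    m = int(np.argmin(dist))
                    tie_pairs.append((nid, int(cort_nodes[m]), float(dist[m])))

    out.nodes = np.vstack(nodes)
    out.elements = np.vstack(elements)
    out.material_labels = np.concatenate(labels)
    for name, ids in new_sets.items():
        out.element_sets[name] = np.asarray(ids, dtype=np.int64)
    out.metadata["tie_pairs"] = tie_pairs
    out.metadata["tie_tolerance"] = float(tie_tolerance)
    out.validate()
    return out
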