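# Methods

This note documents the models, numerical choices and limitations of
`mandifem` at the level a maintainer or reviewer needs.  Units are
consistent N–mm–MPa throughout; tabulated muscle quantities (cm³, cm,
N/cm²) are converted at ingestion.

## Surrogate anatomy

The analysis the package implements depends on the *topology and
labelling* of the mandible — which regions are loaded, constrained,
fractured, plated and averaged over — not on any one specimen's shape.
Subject-specific CT/MRI geometries are therefore replaced by a
parametric surrogate built from mapped structured hexahedral grids split
into six tetrahedra per cell (all cells split around the same body
diagonal, which makes neighbouring face diagonals coincide and the mesh
conforming).  Components:

- **Body**: a horseshoe swept along a circular arc (`arch_radius`,
  centreline arc length `body_length`) with a rectangular cross-section
  (`body_width` × `body_height`).  The chin sits at −Y, posterior ends
  toward +Y, +X is the anatomical right, Z vertical — chosen so the
  muscle direction-cosine tables (where the posterior temporalis has a
  positive Y component) act anatomically correctly.
- **Rami**: vertical extrusions of the posterior 11 % of each half-arc,
  with a top profile that rises into a condylar prominence posteriorly
  and a coronoid prominence anteriorly, separated by a Gaussian notch
  (depth 0.35 × `ramus_height`).
- **Cortical shell / trabecular core**: elements within
  `cortical_thickness` of the outer surfaces are cortical; grid
  breakpoints are *snapped* to the cortical interfaces so the two-phase
  geometry is identical at every mesh resolution (see Convergence).
- **Sheep variant**: elongated body with a toothless diastema span whose
  cross-section tapers to 0.60 × width and 0.65 × height with a smooth
  cosine ramp.  The slender waist is the structural feature that
  concentrates strain in the diastema relative to the tooth-bearing
  body; without it a uniform-section surrogate cannot show the
  diastema/body contrast the comparison is about.

Default dimensions (human 100 × 14 × 25 mm body, 40 mm rami; sheep
200 × 22 × 34 mm body, 48 mm rami, 45 mm diastema) were chosen once so
that the sheep surrogate is more than twice as long and more than three
times the volume of the human one — the two published geometric
constraints — and are ordinary config defaults, not hard-coded.

Occlusal groups (incisor/premolar/molar per side, plus the
first-molar/second-premolar "uni" group) and muscle attachment patches
(SM, DM, AT/MT/PT or lumped TEMP, MPt, LPt per side) are node sets laid
out in the normalized per-side arc coordinate and on ramus surfaces;
muscle patches are constructed disjoint from each other and from the
fixed condylar sets, so no node ever carries both a load and a
conflicting constraint.  An optional seeded jitter perturbs strictly
interior body nodes (amplitude a fraction of the smallest cell, so thin
cortical cells cannot invert); it defaults to 0, giving perfectly
symmetric meshes.  Generation is deterministic for fixed parameters and
seed.

Teeth are not separate organs: the occlusal surface is part of the
cortical continuum, consistent with treating teeth and cortical bone as
one material.

## Muscle loading and clenching tasks

Muscle forces follow `PCSA = V / l_f` and `F = A·K·PCSA` with
`K = 40 N/cm²`.  The registry (`data/muscle_registry.yaml`) stores the
published tables verbatim: maximum forces, right-side direction cosines
(left flips X; printed cosines have Euclidean norm within 0.98–1.02 of
unity and are used unnormalized), and per-task activations at their
2-decimal rounding.  One known inconsistency is preserved deliberately:
the sheep medial pterygoid volume/fiber-length ratio is 4.058 cm² while
the tabulated PCSA is 4.068 cm² (whose product with K reproduces the
tabulated 162.7 N force); the registry keeps the tabulated values and
the test suite pins the 0.010 cm² mismatch rather than forcing the
ratio to agree.  The sheep temporalis is one lumped group whose
activation is the arithmetic mean of the three human temporalis
activations; recomputing the lumped values from the human rows
reproduces the sheep table at 2 decimals for every task and side.

Each muscle's total force `A·F_max` along its direction cosines is
shared **equally over the nodes** of its attachment patch.  How the
force is spatially distributed is not specified by the source tables;
equal shares are deterministic and mesh-auditable, and the quantities
reported here (region averages away from the patches, reaction sums) are
insensitive to the within-patch distribution.  Consistent
area-weighted tractions are available separately
(`fem.uniform_traction`) and are what the verification oracles use,
because constant-stress patch tests require consistent loads.

Boundary conditions: both condylar node sets are fixed in all three
translations ("restrained in all six degrees of freedom" is realized
this way because solid elements carry no rotational DOFs and clamping a
node patch suppresses its rigid rotation), and the task's occlusal sets
are fixed vertically (Z).  UNI's working side defaults to the right
body; a mirrored option exists.

Bite force is reported as minus the vertical reaction sum over the
occlusal sets (positive in closing).  Absolute bite forces and strain
magnitudes are geometry-specific; on the surrogate they land in the
physiologically plausible range (healthy body averages of order
10² με, bite forces of order 10² N, sheep INC markedly weaker than
human INC) but are *not* expected to match any published specimen values
— the tests therefore assert structure (linearity, equilibrium bounds,
cross-model orderings), not magnitudes.

## Finite elements

Small-strain, geometrically linear, isotropic elasticity.  4-node tets
use exact single-point (constant-strain) integration; 10-node tets a
4-point Gauss rule, which is exact for their stiffness here because
mid-side nodes are always inserted at edge midpoints, keeping the
isoparametric map affine.  Assembly is vectorized in fixed chunks with a
fixed ordering, so repeated runs are bitwise identical; the assembled
operator is symmetrized exactly and annihilates precisely the six
rigid-body modes before constraints.

Dirichlet constraints are imposed by row/column elimination (not
penalty), tie constraints by eliminating slave DOFs onto their masters
as translational node-to-node rigid links (no rotational arm).  Masters
may not themselves be slaves; pairs farther apart than the stored
proximity tolerance are rejected with the offending pairs listed.  The
default linear solve is a sparse LU factorization (problem sizes up to
~10⁵ DOFs); a solve that leaves rigid modes raises a singular-system
error naming the missing boundary conditions, and every successful
solve asserts a global equilibrium residual below 1e-8 per axis.

Strain/stress recovery is element-constant: the constant strain of a
linear tet, or the equally-weighted (= volume-weighted, as the Jacobian
is constant) average of the four Gauss-point strains of a quadratic tet.
Element-constant values make region averaging unambiguous.  Principal
strains are sorted eigenvalues of the symmetric strain tensor; von Mises
stress comes from the stress deviator.

Verification oracles (all in the test suite): symbolic single-element
stiffness via an independent sympy integration; uniaxial patch test
exact to 1e-9 for both orders; cantilever tip deflection within 5 % of
`PL³/3EI` on a quadratic mesh with four elements through the depth (and
quadratic beating linear at equal edge length); serial two-material bar
against closed-form compliances; tied two-body patch test matching the
monolithic mesh to 1e-6; principal-strain invariance under rigid
rotation of model plus loads.

## Fracture and fixation

A fracture is a **material swap**: every element whose centroid lies
within half the gap width (default 1.5 mm) of the transverse plane —
and within a capture radius that keeps the infinite plane from also
cutting the contralateral body — is reassigned to granulation tissue
(1 MPa), emulating the earliest healing phase.  No mesh splitting or
contact.  The gap set must sever the load path: removing it has to
split the element-adjacency graph in two, otherwise the mesh is too
coarse across the gap.  For the fracture scenarios the generator
refines the grid in a band around the plane and snaps two breakpoints
0.9 × gap width apart across it, so one full column of element
centroids always falls inside the slab.

Scenario presets: `human_body` and `sheep_body` fracture the left body
between the last premolar and first molar; `sheep_diastema` fractures
the distal (posterior) end of the diastema.

Fixation appends two parallel 4-hole miniplates (24 × 4 × 1 mm,
generated in the same swept-arc coordinates as the bone so they sit
flush-bent on the buccal surface, stress-free) and eight screws (2 mm
square section standing in for the 2.0 system's cylindrical shank,
7 mm long: 1 mm through the plate, 6 mm into bone).  Bonding uses
recorded node-to-node tie pairs — screw ends to the nearest plate node,
screw shaft to the nearest **cortical** bone node within the cortical
depth only (monocortical by construction); plates never tie directly to
bone.  Conformal screw–bone meshing was considered and rejected: on the
structured bone grid it would distort cells near every screw, whereas
the tie fallback keeps the bone mesh intact and its error is absorbed
into the singularity-excluded implant statistic (below).

Properties asserted instead of absolute magnitudes: the gap's average
principal-strain magnitude exceeds the adjacent bone's by ≥10× (the
1 vs 300+ MPa modulus contrast guarantees compliance concentration);
attaching hardware strictly lowers the gap's mean principal-strain
magnitude for every task (the mean of |ε₁| and |ε₃| — buccal plating
shifts the neutral axis, so the tensile average alone can rise while
the overall deformation drops); and the most stressed element of the
two plates lies closer to the fracture plane than half the
gap-bridging screw spacing.  The per-plate raw argmax is not asserted:
on the less-loaded plate it can sit at a screw-tie stress
concentration, the same artefact class the peak statistic excludes.

## Reported statistics

- **Region strain summaries**: volume-weighted element averages of ε₁
  and ε₃ over a named element set, reported in microstrain (strains are
  stored dimensionless and scaled 1e6 at output).  Volume weighting
  removes mesh-density bias; with element-constant fields it equals the
  exact volume integral divided by region volume.
- **Implant peaks**: per implant set, sort von Mises descending, drop
  the top `ceil(0.001·N)` values (at least one, hence ceil — the
  rounding convention is pinned by test) as tie-constraint
  singularities, average the next ten, compare against 880 MPa.  The
  exclusion is per-implant, and both plates are reported individually
  plus their maximum.
- **Bite force**: minus the vertical occlusal reaction sum.

## Mesh convergence protocol

A refinement ladder of target edge lengths (coarse → fine, ≥3 levels)
is generated, converted to quadratic elements, loaded with the
simplified masseter load — total (Fx, Fy, Fz) = (0, −50, 50) N spread
over the buccal nodes within a 10 mm radius of each superficial-masseter
patch centroid, condyles fixed — and solved; the body-averaged von Mises
stress and principal strains of each level are compared with the finest
level, accepting the coarsest level with all relative errors below 5 %.
The simplified load removes muscle-attachment variability from the
protocol.

Because all grid breakpoints snap to the anatomical feature and
cortical-interface coordinates, every ladder level discretizes the
*identical* two-phase geometry; without that, O(h) wobble of the
cortical volume dominates the error and the protocol measures geometry
noise instead of discretization error.  On the default human ladder
(8, 6.3, 5, 4 mm; finest ≈ 6·10³ quadratic tets, ≈ 3·10⁴ DOFs — sizes
chosen so the whole protocol runs in seconds on one core) the
second-finest level agrees with the finest to well under 5 % on all
three metrics, mirroring the accept-the-second-finest-mesh criterion.

## Orchestration

`run_scenario` composes generate → (fracture + fixate) → load → solve →
metrics for one (scenario, task) and emits a bundle: summary tables,
implant peaks, bite force, mesh/load-case/fields files and a provenance
record (config hash, seed, library versions, DOF count, equilibrium
residual).  `run_paper_suite` executes the 15-run comparison matrix
(2 healthy species × 3 tasks + 3 fracture scenarios × 3 tasks),
collects per-run failures into a manifest instead of aborting, and
emits the three comparison tables (healthy strains, gap strains,
implant stress).  Everything is deterministic: identical configurations
reproduce byte-identical tables.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the *method* is implemented correctly
(verified solver, exact statistics, faithful load/constraint
definitions) and that the *structural* comparisons hold on matched
surrogate anatomies: sheep body strains below human body strains for
every task, diastema strains above sheep-body strains when the diastema
lies in the load path (INC, UNI — under ICP the molar bite bypasses the
diastema on the surrogate, so that ordering is geometry-dependent and
not asserted), strain concentration and stiffening at fixated
fractures, implant peaks far below yield.  They do not validate
specimen-specific magnitudes: real mandibles have varying cortical
thickness, curved occlusal planes, periodontal structures and
muscle-wrapping geometry the surrogate omits, and published absolute
strain/stress/bite values depend on those.  Further known limitations:
linear elasticity only (yield is a reporting threshold, not a material
model), no TMJ contact (condyles rigidly fixed), no screw preload or
thread mechanics, node-to-node ties rather than surface ties, and no
orthotropic cortical bone.
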