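# mandifem

Comparative mandibular biomechanics on parametric surrogate geometries:
a finite-element pipeline for judging the sheep mandible as a preclinical
test bed for human mandibular fracture-fixation devices.

Fixation of simple mandible fractures is routinely done with titanium
miniplates and monocortical screws; new devices are evaluated in large
animal models first, but whether a plated fracture in a sheep jaw sees
the same mechanical environment as in a human jaw is an open question.
This package lets a biomechanics researcher reproduce that comparison at
desk scale: it builds labelled human-like and sheep-like mandible models,
loads them with physiological jaw-closing muscle forces under three
clenching tasks, solves the linear-elastic problem for healthy and
plate-fixated fractured bone, and reports the summary statistics used to
compare the two species — region-averaged principal strains (the
mechanical signal that drives bone healing), implant von Mises peaks
against the 880 MPa titanium yield threshold, and occlusal bite forces.

## The model

**Muscle forces.** Each jaw-closing muscle (superficial/deep masseter,
temporalis, medial/lateral pterygoid) exerts

```
PCSA = V / l_f            (physiological cross-sectional area, cm^2)
F    = A · K · PCSA       (muscle force, N)
```

with muscle volume `V` (cm³), fiber length `l_f` (cm), the
musculoskeletal constant `K = 40 N/cm²`, and the task-specific fiber
activation `A ∈ [0, 1]`.  Forces act along tabulated direction cosines
(the left side mirrors the right in X) and are distributed over labelled
attachment patches.  The sheep temporalis is lumped: its activation is
the mean of the three human temporalis activations.

**Clenching tasks.** Static bite = displacement constraints: ICP
(intercuspal) fixes all molars/premolars vertically, INC (incisal) the
incisors, UNI (unilateral) the first-molar/second-premolar group of the
working (right) side.  Condylar node sets are fully restrained.

**Tissues.** Isotropic linear elasticity: cortical bone 15,000 MPa
(human) / 15,750 MPa (sheep), trabecular 300 MPa, fracture-gap
granulation tissue 1 MPa (all ν = 0.30), Ti-6Al-4V hardware 110,000 MPa
(ν = 0.34).  A fracture is a 1.5 mm transverse band of elements swapped
to granulation tissue; fixation is two parallel 4-hole miniplates (1 mm
thick) with four 7 mm monocortical screws each, bonded by tie
constraints (plate↔screw, screw↔cortical bone).

**Solver.** 4-node (C3D4-style) and 10-node (C3D10-style) tetrahedra,
sparse direct solve, element-constant strain/stress recovery, principal
strains and von Mises stress per element.  Implant peaks exclude the top
0.1 % of values as tie-constraint singularities and average the next ten.

Since the study's CT/MRI geometries are not available, a first-class
synthetic-anatomy generator supplies watertight surrogate mandibles
(horseshoe body, rami with condylar/coronoid prominences, cortical shell
over trabecular core, sheep variant with an elongated body and a slender
toothless diastema) carrying every node/element set the analysis needs.
Absolute strain/stress magnitudes are geometry-specific and are not
reproduced; the cross-model structure of the analysis is.

## Worked example

Solve the plated sheep-diastema fracture under unilateral clenching:

```bash
mandifem solve --scenario sheep_diastema --task UNI --out runs/diastema_uni
```

prints (10-node elements, default sheep anatomy):

```
            region  avg_max_principal  avg_min_principal task side
   mandibular_body         233.152666        -254.005204  UNI   NA
   diastema_region         271.136103        -340.178197  UNI   NA
      fracture_gap       10160.748631      -13320.092240  UNI   NA
mandibular_body_WS         115.993317        -117.394475  UNI   WS
mandibular_body_BS         350.290086        -390.590363  UNI   BS
bite force: 332.3 N
      implant  peak_von_mises  exceeded_yield
    plate_top       42.719186           False
 plate_bottom       43.805782           False
max_of_plates       43.805782           False
```

Reading this: strains are in microstrain (με).  The compliant
granulation gap concentrates deformation (~10,000 με, the regime that
drives early callus formation) while the surrounding body stays near
physiological levels (~250 με); the balancing side (BS) carries more
strain than the working side (WS), whose occlusion is supported; and the
plate peaks (~44 MPa) stay far below the 880 MPa titanium yield, so no
hardware failure is predicted.  `runs/diastema_uni/` contains the
summary tables (CSV), the load case and mesh (Abaqus-.inp subset), the
fields (VTU) and a provenance record.

Other entry points: `mandifem generate` (meshes only), `mandifem suite`
(the full 15-run healthy + fracture comparison matrix with the
cross-species tables), `mandifem converge` (mesh-refinement protocol),
and `mandifem solve --config run.yaml` for scripted configurations.

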