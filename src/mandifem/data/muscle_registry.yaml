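# Jaw-closing muscle registry: maximum forces (N), direction cosines of the
# right-side line of action (X transverse, Y antero-posterior, Z vertical;
# the left side flips the X component), and fiber activation ratios A per
# clenching task (ICP intercuspal, INC incisal, UNI unilateral with
# right working side / left balancing side).
#
# Sheep maximum forces derive from MRI-based physiological cross-sectional
# areas via F = A*K*PCSA with K = 40 N/cm^2 and A = 1; volume (cm^3) and
# fiber length (cm) are kept so the PCSA chain can be recomputed.  The
# sheep temporalis is lumped: its activation is the mean of the human
# anterior/medial/posterior temporalis activations.  Note the medial
# pterygoid row: volume/fiber length = 4.058 cm^2 while the tabulated
# PCSA is 4.068 cm^2 (consistent with the 162.7 N force); the tabulated
# values are stored verbatim.
human:
  - name: superficial_masseter
    set: SM
    max_force: 190.4
    direction: [-0.207, -0.419, 0.884]
    activation: {ICP: [1.0, 1.0], INC: [0.40, 0.40], UNI: [0.72, 0.60]}
  - name: deep_masseter
    set: DM
    max_force: 81.6
    direction: [-0.546, 0.358, 0.758]
    activation: {ICP: [1.0, 1.0], INC: [0.26, 0.26], UNI: [0.72, 0.60]}
  - name: anterior_temporalis
    set: AT
    max_force: 158.0
    direction: [-0.149, -0.044, 0.988]
    activation: {ICP: [0.98, 0.98], INC: [0.08, 0.08], UNI: [0.73, 0.58]}
  - name: medial_temporalis
    set: MT
    max_force: 95.6
    direction: [-0.222, 0.500, 0.837]
    activation: {ICP: [0.96, 0.96], INC: [0.06, 0.06], UNI: [0.66, 0.67]}
  - name: posterior_temporalis
    set: PT
    max_force: 75.6
    direction: [-0.208, 0.855, 0.474]
    activation: {ICP: [0.94, 0.94], INC: [0.04, 0.04], UNI: [0.59, 0.39]}
  - name: medial_pterygoid
    set: MPt
    max_force: 174.8
    direction: [0.486, -0.373, 0.791]
    activation: {ICP: [0.76, 0.76], INC: [0.78, 0.78], UNI: [0.84, 0.60]}
  - name: lateral_pterygoid
    set: LPt
    max_force: 66.9
    direction: [0.630, -0.757, -0.174]
    activation: {ICP: [0.27, 0.27], INC: [0.71, 0.71], UNI: [0.30, 0.65]}
sheep:
  - name: superficial_masseter
    set: SM
    max_force: 292.5
    volume: 87.1
    fiber_length: 11.911
    pcsa: 7.313
    direction: [-0.054, -0.840, 0.539]
    activation: {ICP: [1.0, 1.0], INC: [0.40, 0.40], UNI: [0.72, 0.60]}
  - name: deep_masseter
    set: DM
    max_force: 136.4
    volume: 12.4
    fiber_length: 3.636
    pcsa: 3.410
    direction: [-0.539, -0.248, 0.805]
    activation: {ICP: [1.0, 1.0], INC: [0.26, 0.26], UNI: [0.72, 0.60]}
  - name: temporalis
    set: TEMP
    max_force: 165.9
    volume: 40.8
    fiber_length: 9.837
    pcsa: 4.148
    direction: [0.036, 0.840, 0.541]
    activation: {ICP: [0.96, 0.96], INC: [0.06, 0.06], UNI: [0.66, 0.55]}
  - name: medial_pterygoid
    set: MPt
    max_force: 162.7
    volume: 42.8
    fiber_length: 10.547
    pcsa: 4.068
    direction: [0.186, -0.083, 0.979]
    activation: {ICP: [0.76, 0.76], INC: [0.78, 0.78], UNI: [0.84, 0.60]}
  - name: lateral_pterygoid
    set: LPt
    max_force: 62.8
    volume: 4.7
    fiber_length: 2.993
    pcsa: 1.570
    direction: [0.400, -0.716, 0.574]
    activation: {ICP: [0.27, 0.27], INC: [0.71, 0.71], UNI: [0.30, 0.65]}
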