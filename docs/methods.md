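# Methods

This note records the modelling choices behind `fractwin`: what is
simulated, under which assumptions, which defaults matter, and what the
synthetic data can and cannot show.

## Scope and assumptions

The pipeline estimates two quantities per weight-bearing level on a plated
tibia: the peak von Mises stress in the implant (checked against the
material yield strength) and the distribution of mechanical stimulus in the
fracture gap (checked against a tissue-differentiation "healing window").
The mechanical model is deliberately linear:

- small-strain isotropic elasticity, no material or geometric nonlinearity;
- tied interfaces everywhere — bone, gap and implant share mesh nodes, so
  there is no screw–bone contact, pretension or sliding;
- static solves per gait sample; inertia is neglected (gait loading is slow
  relative to the construct's dynamics);
- units are mm–N–MPa throughout (1 N/mm² = 1 MPa), so no conversion factors
  appear anywhere.

Linearity is not just an assumption but the computational backbone: three
unit-load systems (1 N total along each axis, distributed over the proximal
node set) are factorized and solved once; every amplitude sample of every
weight-bearing level is a linear combination. A per-sample re-solve mode
exists solely as an independent cross-check and agrees to solver precision.

## Synthetic phantom

Patient CT and motion data are not distributable, so a generator produces
the study inputs. The phantom is a simplified axisymmetric tibia shaft:
cortical tube (outer radius 12 mm, inner 7 mm, ~1200 HU), trabecular core
(~300 HU), a transverse soft fracture gap (3 mm, ~50 HU), a lateral plate
with four transverse screws painted at metal HU (3000), and six calibration
rods (0–800 mg HA/cm³) painted through the inverse of a known linear
HU–density map (defaults: ρ = 0.8·HU − 2 mg/cm³). Per-tissue HU scatter and
global Gaussian noise (default sd 10 HU) are seeded; a fixed seed gives
byte-identical volumes.

What the phantom does *not* emulate: real anatomy (curved shafts, condyles,
intra-articular fracture lines), CT physics (beam hardening, metal
artifacts, partial-volume blur), and surgeon-corrected segmentations.
Passing tests therefore demonstrate the correctness of the *computational
chain* — calibration, thresholding, meshing, material mapping, solving,
classification — not the clinical accuracy of any specific patient model.
The segmentation stage would in particular need artifact handling before
touching real metal-implant CT.

Gait loading is likewise synthetic: two-peak stance-phase knee-force curves
(PCHIP through fixed control points, so configured peaks are attained
exactly; peaks at 15% and 45% of the cycle, stance ends at 62%). Default
axial peaks are 100/90 %BW for the 20-kg level — a 20 kg partial load is
known to drive knee contact force to roughly one body weight — 180/160 %BW
at 50% body weight, and 260/240 %BW at full weight-bearing, in the range of
reported knee contact forces for free gait. Shear components default to 12%
(anterior–posterior) and 5.5% (medio-lateral) of the axial peaks. A cohort
of 22 seeded curves per level is averaged into the reference database.

## Numerical choices

- **Meshing.** Labelled voxels are split into five tets (parity-alternating
  mirror variants so shared faces match; a six-tet Kuhn mode exists). Total
  tet volume equals labelled voxel volume to 1e-9 relative; all tets are
  positively oriented. Distal/proximal node sets take the lowest/highest 2%
  of the z-extent by default; convergence studies shrink this to one node
  layer so the set does not smear across layers on fine grids.
- **Elements.** Constant-strain TET4 baseline; optional TET10 via midside
  insertion with 4-point Gauss quadrature. Strain is reported per element
  (the volume-averaged B matrix for TET10), because the assessment consumes
  one tensor per tet.
- **Load distribution.** The total force is split *equally* across the
  proximal nodes by default. Equal splitting is not a consistent nodal
  load, so it perturbs the stress field near the loaded face
  (Saint-Venant); a tributary-area ("consistent") mode exists and is used
  for analytic verification, where it reproduces the uniaxial closed form
  to machine precision.
- **Constraints.** Dirichlet conditions are imposed by row/column
  elimination (exact), then the reduced SPD system is factorized with a
  sparse LU. Reactions are recovered as K·u − f on the fixed DOFs; the
  equilibrium residual is checked on every solve.
- **Material mapping.** Element HU is the mean over voxel centres inside
  the element with a centroid fallback; on voxel-decomposition meshes both
  rules reduce to the source voxel's HU, and a fast path exploits that.
  Negative calibrated densities are clamped to zero before the power laws.
  Note the default trabecular/cortical law pair is discontinuous at the
  ρ_ash = 0.6 g/cm³ split (a known property of these literature laws):
  modulus is monotone in HU within each branch, and the phantom's tissue HU
  distributions do not straddle the split.
- **Thresholds** use half-open, lower-inclusive intervals everywhere
  (segmentation and healing window) for deterministic tie-breaking.

## Healing window

The numeric boundaries of the tissue-differentiation window are scientific
inputs, not constants; the shipped default is a documented surrogate in the
Claes–Heigele spirit: intramembranous ossification for γ_oct < 5% and
|ε_vol| < 5%; endochondral ossification for 5% ≤ γ_oct < 15% under
compression (−15% ≤ ε_vol < 0); connective tissue (unfavorable) elsewhere.
The configuration is a list of rectangles in (γ_oct, ε_vol); several
rectangles may share a class. At load time the partition is verified on a
200×200 grid over γ_oct ∈ [0, 1], ε_vol ∈ [−0.5, 0.5]: every point must
belong to exactly one class. Class fractions are volume-weighted with the
element volumes; the healing verdict compares the worst-over-cycle
unfavorable fraction against a configurable limit (default 0, i.e. any gap
volume outside the window flags the level). The gap is modelled as very
early granulation tissue (E = 3 MPa), so gap strains are large and the
default phantom is typically "unfavorable" at every level — the informative
output at desk scale is the *ordering and scaling* across levels, which is
exactly linear in the applied load.

## Problem sizes and determinism

The default phantom is 32×32×80 voxels at 1.875 mm (~58k tets, ~46k DOFs);
a full three-level run takes seconds to tens of seconds on one CPU. Tests
use a 20×20×40 voxel phantom at 3 mm (~11k tets). All randomness flows from
one run seed through `numpy` seed sequences; identical configuration and
seed reproduce byte-identical reports. Stage outputs (mesh + materials) are
cached on disk keyed by a hash of the scientific configuration (output
paths and I/O toggles excluded), so the FE stage can be iterated without
re-segmentation.

## Known limitations

- No callus evolution: the window classifies the instantaneous elastic
  stimulus; it does not simulate tissue differentiation over healing time.
- No contact, screw pretension, or interface failure; tied interfaces make
  the construct stiffer than reality.
- The .inp dialect and VTU reader/writer cover the subset this pipeline
  emits (documented in the module docstrings), not the full grammars.
- Reference gait curves are synthetic defaults; user-supplied curves in the
  documented CSV schema (`t_frac,Fx,Fy,Fz` in %BW) replace them directly.
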