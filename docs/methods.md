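# Methods

## The problem the package models

In pressure-overloaded ventricles (severe aortic stenosis) the extracellular
volume fraction (ECV) measured by CMR rises after valve replacement even
though patients do well.  Whether that rise means diffuse fibrosis or simply
reflects shrinking myocytes cannot be decided from imaging alone.  The
modelling route taken here couples three tissue parameters to ventricular
conduction and fits them to each patient's QRS duration:

- **R** — myocyte radius (µm), the degree of cellular hypertrophy.  With
  myocytes idealized as cylinders, the surface-to-volume ratio is
  `beta = 2/R` (cm⁻¹), so a larger radius lowers the membrane load per unit
  volume and speeds conduction.
- **ECV** — extracellular volume fraction (0–1).  Scales the extracellular
  conductivity relative to a reference ECV.  A measured input, never fitted.
- **ECF** — extracellular conductivity factor (0–1).  Fraction of the
  extracellular current path occluded by fibrotic content: 0 leaves the
  extracellular conductivities unaltered, 1 makes the extracellular space
  non-conductive.

## Conductivity mapping

Per axis (fiber, transverse, sheet-normal):

```
sigma_e_eff = sigma_e0 * (ECV / ECV_ref) * (1 - ECF)
sigma_i_eff = sigma_i0
sigma_mono  = sigma_i_eff * sigma_e_eff / (sigma_i_eff + sigma_e_eff)
D           = sigma_mono / (beta * Cm)          # cm²/ms
```

Defaults (`src/cardiotwin/data/baseline_conductivities.yaml`): Clerc-type
conductivities `sigma_i = (0.17, 0.019, 0.019)` S/m,
`sigma_e = (0.62, 0.24, 0.24)` S/m (monodomain fiber:transverse anisotropy
≈ 7.6), `Cm = 1 µF/cm²`, references `R_ref = 15.45 µm`, `ECV_ref = 25.8 %`
— the identity point at which the mapping returns the baseline values
unchanged.  The exact functional form of the ECV/ECF scaling is a modelling
choice grounded in volume-fraction cable theory (extracellular conductance
proportional to the conducting extracellular volume); it reproduces the
qualitative behaviour the parametrization requires — CV rising with R and
ECV, falling with ECF, propagation failing at ECF = 1 — and is isolated in
`effective_conductivity` so an alternative law can be swapped in.  Whether
ECF should scale all extracellular axes equally, and whether intracellular
conductivity should also be ECV-normalized, are open choices; the defaults
scale all extracellular axes equally and leave the intracellular tensor
untouched.

## Membrane model

Human ventricular kinetics follow the ten Tusscher–Panfilov (2006)
formulation, 19 state variables, with the published epicardial parameter set
as the tissue default (endocardial and mid-myocardial variants are
available; transmural heterogeneity is not enabled by default because the
QRS surrogate used here — total activation time — is insensitive to
repolarization gradients).  Integration uses Rush–Larsen exponential updates
for the twelve gates and forward steps with analytic rapid-buffering
corrections for the calcium subsystem; `dt = 0.02 ms` in tissue, `0.001 ms`
available for reference runs.  Gates are clamped to [0, 1] each step.
Stimuli are transmembrane current injections in pA/pF (numerically mV/ms);
the default tissue stimulus is 100 pA/pF for 2 ms, single-cell protocols use
52 pA/pF (about twice diastolic threshold for a 2 ms pulse).

## Forward engines

**Reference: monodomain.**  Operator-split reaction–diffusion.  In 1-D
(strands) an explicit finite-difference diffusion with stability-sized
substeps; in 3-D, P1 tetrahedral finite elements with lumped mass and a
backward-Euler diffusion solve (prefactorized sparse LU), diffusion step
0.1 ms (0.02 ms where engine cross-checks demand tighter splitting).
Activation is the first upward crossing of 0 mV (configurable), linearly
interpolated in time.  The full-ionic mode refuses meshes with a lattice
resolution coarser than 0.5 mm: the depolarization wavefront (≈ 0.5 mm at
60 cm/s) must be resolved or the discrete CV collapses.  The quiescent
interval (default 1000 ms) is integrated as a single uniform cell and
broadcast, which is exact for uniform resting tissue and removes the
dominant cost of the protocol's equilibration phase.

**Fast surrogate: anisotropic eikonal.**  First-arrival times on the
tetrahedral mesh, with per-element slowness metrics built from the fiber
frame and the three axis CVs.  The solver is a label-correcting relaxation
(FIFO queue seeded in approximately causal order): each node is repeatedly
updated from the opposite faces of its incident tetrahedra, combining the
causal linear-front solve per face with closed-form edge and vertex
fallbacks.  Nodes within four edge lengths of a source are initialized with
the exact local metric distance, removing the frozen point-source error of
purely local solvers.  Verified accuracy on lattice meshes: ≤ 2 % against
the closed form for a uniform-speed point source.  Known artifact: where
two fronts collide, the face interpolation mixes values from both fronts
and can undershoot the true first arrival by up to about one cell of travel
time; away from collision zones multi-source solutions equal the pointwise
minimum of single-source solutions.

**Calibration.**  `CvCalibrator` links the engines: the CV for a given
diffusivity is measured on a fine monodomain strand (spacing 0.1 mm,
probes at 35 % and 75 % of a 20 mm strand).  Because the cable equation is
exactly self-similar under `x -> s*x, D -> s²*D` and the strand spacing is
scaled with `sqrt(D)` to keep the discretization error constant, a single
calibrated reference run determines `CV(D) = CV_ref * sqrt(D / D_ref)`
(mode `"scaled"`, the default); mode `"direct"` runs one strand per
diffusivity and is used by the sensitivity suite and in validation tests.
For engine cross-checks on coarse 3-D meshes the strand is run at the mesh's
own spacing, since the purpose there is to reproduce what the discrete
monodomain engine does at its operating resolution.

## QRS surrogate and CV measurement

The model's QRS duration is the **total activation time**: latest nodal
activation minus earliest stimulus onset, under simultaneous pacing at five
endocardial early-activation sites (two LV septal, LV anterior paraseptal,
LV inferior free wall, RV septal — positions in ventricular coordinates,
configurable; the defaults are a documented stand-in, since published
coordinates for this pattern are not available).  Conduction velocity is
measured under RV apical pacing between two probes on the RV septal
endocardium separated by ≈ 20 mm of geodesic distance along the apicobasal
axis; the probe pair is constrained to one rotational line because a
circumferential detour would lie along an isochrone of the apex-paced front
and inflate the apparent CV.  CV = geodesic distance / activation delay;
a negative delay (front arriving basally first) flags the measurement
invalid.

## Idealized anatomy

Patient meshes are out of scope; geometry is an idealized biventricle: a
thick-walled truncated LV ellipsoid (default outer semi-axes 30×30×42 mm,
10 mm wall) intersected by a thin-walled RV ellipsoid (5 mm free wall,
half-thickness apical cap so the RV cavity reaches its apex), truncated at
a base plane.  The septum is the part of the LV wall facing the RV cavity.
The implicit geometry is voxelized at the target edge length and each cube
split into six tetrahedra (Kuhn subdivision, conforming across cubes); the
largest connected component is kept.  A global `scale` shrinks all lengths
for desk-scale work.

Ventricular coordinates: transmural by a Laplace solve (endo 0, epi 1; in
the septum the RV-facing surface takes the epicardial role); apicobasal by
normalized geodesic distance `d_apex/(d_apex+d_base)` per ventricle (a pure
Laplace solve with a small apex patch concentrates nearly the whole range
at the apex); rotational by the angle about the long axis with origin at
the anterior LV–RV junction.  Fibers follow the standard rule — helix angle
linear in the transmural coordinate from +60° (endo) to −60° (epi) —
applied in a per-element frame built from the coordinate gradients.  The
AHA division cuts apicobasal bands at 1/3 and 2/3 (apex cap below 0.12) and
60°/90° rotational sectors.  Wall thickness per segment is the
endocardial-surface-to-outer-surface nearest distance averaged over the
segment's endocardial faces (area-weighted); for septal segments the
"outer" surface is the RV-facing septal endocardium.  The apex-cap segment
may carry no endocardial surface (the cavity ends above the cap) and is
then reported missing, not zero.

## Two-step personalization

Inputs per patient and time point: QRS duration (target), ECV (set), LV
average wall thickness.  The pre/post radius ratio is fixed before fitting:

```
rho = sqrt( WT_post (1 - ECV_post) / [ WT_pre (1 - ECV_pre) ] )
```

from conservation — myocyte volume per wall area ∝ WT·(1−ECV), with cell
count and length assumed unchanged, and volume ∝ R².  The formula is
isolated in `relative_radius_change` so an alternative bookkeeping can be
dropped in; everything downstream depends only on `rho`.

Step 1 finds the **shortest** admissible `R_pre` (QRS(R) is strictly
decreasing, asserted before fitting) such that both models' QRS is no
longer than their targets, with `R_post = rho * R_pre` and both radii
inside the histological range 9.6–17.8 µm.  The admissible set is an
interval, so a bisection to 0.05 µm suffices; an exhaustive-grid oracle is
kept in the tests.  When both time points constrain the radius, the larger
of the two minimal radii binds — the only reading under which "no longer
than the target" holds for each model.  Step 2 raises ECF in 5 % steps,
independently per time point, to minimize |model QRS − target|; ties break
toward smaller ECF, and since QRS(ECF) is non-decreasing the walk stops at
the first worsening step.  If even the largest radius leaves the QRS above
target, the bound is returned flagged and the ECF stage reports the
residual at ECF = 0.

Identifiability: step 1 drives QRS(R, ECF=0) onto the target, so ECF > 0
can only be recovered at a time point whose radius constraint is *not* the
binding one (typically the ratio constraint leaves one time point with
slack, which ECF then closes).  A time point with true ECF > 0 *and* a
binding radius is not identifiable by this method — an inherent property
of the two-step design, not of this implementation.

## Synthetic cohort

The generator emulates the paired pre/post structure of a 12-patient
valve-replacement cohort: truncated-normal draws with ECV_pre centred at
24 % (SD 3) rising by ~4 points (SD 2) after surgery; wall thickness
11.6 mm (SD 1.5) shrinking by 21 % (SD 5) in females and 8 % (SD 4) in
males; true R_pre centred at 13.8 µm (SD 1.5) truncated so both radii fit
the admissible range under the drawn `rho`; LV volume ~120 mL, BSA
~1.9 m².  "Patient" QRS durations are produced by the forward model at the
true parameters (optional Gaussian measurement noise, default 0 ms), and
candidates whose QRS exceeds 110 ms are redrawn — the cohort's own
inclusion criterion.  The pre-to-post QRS change is consequently only
approximately zero: the conduction slow-down from the shrinking radius and
the speed-up from the rising ECV largely offset, but the residual (plus any
one-sided true ECF) leaves a small systematic QRS increase of a few
milliseconds rather than the exactly unchanged QRS of a matched clinical
cohort.  Because of the identifiability property above, the
generator makes the ground truth recoverable by construction: one time
point per pair is marked *binding* (true ECF = 0) and the other draws a
grid-valued true ECF (uniform on {0, 0.05, …, 0.25}).  Ground truth (radii,
ECFs, rho, binding side) is stored separately from the records.

What the generator does **not** emulate: real geometric remodelling (a
shared idealized mesh stands in for per-patient meshes), QRS morphology,
regional heterogeneity of ECV or fibrosis, and measurement error in wall
thickness or ECV.  Passing recovery tests therefore show that the inverse
method is a faithful inverse of its own forward model under the stated
conditions — not that the parameters are identified in real patients.

## Statistics

Wilcoxon matched-pairs signed-rank, Mann-Whitney, and Spearman correlation,
two-sided throughout, no multiple-testing correction.  Exact p-values by
complete enumeration for small samples (sign assignments up to n = 25;
label assignments / permutations up to n = 8), mid-ranks for ties, zero
differences dropped (all-zero input returns p = 1 flagged degenerate);
normal/t approximations above, flagged.  Quartiles use linear interpolation
between order statistics.  Derived volumes: mass = 1.05 g/mL × LV volume;
matrix = ECV × volume; cells = (1−ECV) × volume; all BSA-indexed.

## Problem sizes and numerical defaults

Chosen as the package's desk-scale operating points: strands 20 mm at
0.1 mm (finer, down to 0.02 mm, when the diffusivity is small); engine
cross-checks on a 12×6×3 mm slab at 0.25 mm with 0.02 ms diffusion steps;
biventricular work on reduced-scale geometries (scale 0.5–0.7, edge
1.2–1.5 mm, ≈ 6–20 k nodes) where one eikonal QRS evaluation takes well
under a second and a full patient personalization a few tens of seconds.
Bisection tolerance 0.05 µm; ECF grid step 5 %; eikonal relaxation
tolerance 1 ns.  All engines are deterministic given their inputs; the only
randomness in the package is the cohort generator's seeded RNG.

## Known limitations

- The ECV/ECF conductivity law and the radius-ratio formula are
  reconstructed modelling choices behind stable interfaces, not asserted
  canonical forms.
- Total activation time is a QRS *surrogate*: no extracellular potentials,
  12-lead ECG or QRS morphology are computed.
- The idealized geometry yields realistic CV but its absolute activation
  times depend on the chosen scale; cross-patient geometric variability is
  not modelled.
- Eikonal collision zones can undershoot first arrivals by ~one cell.
- Active membrane properties are deliberately held fixed across time
  points; the method cannot see changes in sodium channels or gap-junction
  distribution.
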