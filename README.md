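# cardiotwin

Digital-twin personalization of ventricular tissue conductivity from QRS
duration, for studying how post-operative reverse remodelling (shrinking
myocytes, rising extracellular volume) affects cardiac conduction.

Elevated extracellular volume (ECV) on CMR is usually read as diffuse
fibrosis, but ECV also rises when myocytes shrink after aortic valve
replacement.  This package implements the modelling route that separates
the two: tissue conductivity is parametrized by the myocyte radius **R**
(µm), the extracellular volume fraction **ECV**, and the extracellular
conductivity factor **ECF** (fraction of the extracellular path occluded by
fibrosis, 0–1):

```
sigma_e_eff = sigma_e0 · (ECV / ECV_ref) · (1 − ECF)        per axis
sigma_mono  = sigma_i sigma_e_eff / (sigma_i + sigma_e_eff)
D           = sigma_mono / (beta · Cm),     beta = 2 / R
```

so hypertrophy (large R) speeds conduction and fibrosis (large ECF) slows
it.  For each patient and time point, R and ECF are fitted so that the
simulated **total biventricular activation time** — the QRS surrogate under
simultaneous pacing from five endocardial early-activation sites — matches
the patient's QRS duration: first the shortest admissible R (with the
pre/post radii locked to the ratio `rho = sqrt[WT·(1−ECV)]_post/pre` and
bounded by the histological range 9.6–17.8 µm), then ECF in 5 % steps.
Septal conduction velocity is afterwards measured under RV apical pacing
between two probes ~2 cm apart on the RV septal endocardium.

The package is aimed at computational electrophysiologists: it contains an
idealized biventricular mesh generator with ventricular coordinates,
rule-based fibers, AHA segmentation and wall-thickness measurement; the ten
Tusscher–Panfilov (2006) membrane model; a full-ionic monodomain reference
solver and a calibrated anisotropic eikonal engine; the two-step inverse
method; and a synthetic paired pre/post cohort generator with recoverable
ground truth plus the exact nonparametric statistics used to analyse it.
Real CMR segmentation and patient meshes are out of scope.

## Worked example

`examples/05_personalize_patient.py` generates one synthetic patient with
known ground truth and personalizes it end to end:

```
patient SYN001: QRS 58.8 -> 60.1 ms, ECV 0.250 -> 0.264, wall 12.1 -> 10.8 mm
fitted   R_pre 15.16 um (truth 15.16), R_post 14.14 um, ratio 0.933 (exact constraint)
fitted   ECF pre 0.10 (truth 0.10), post 0.00 (truth 0.00)
QRS errors: pre -0.00 ms, post -0.00 ms
septal CV under apical pacing: pre 53.6, post 52.6 cm/s
```

The fitted radius recovers the truth to the 0.05 µm search tolerance, the
post radius is exactly `rho × R_pre`, the fitted ECFs land on the true grid
values, and the remaining QRS errors are sub-millisecond.  (QRS values are
short because the demo geometry is a reduced-scale ventricle.)  The other
examples each demonstrate one capability:

- `01_single_cell.py` — myocyte pacing; prints resting potential
  (−85.4 mV) and APD90 (290 ms at 600 ms cycle length).
- `02_tissue_parameters.py` — the (R, ECV, ECF) → diffusivity mapping,
  including the non-conducting ECF = 1 limit.
- `03_strand_cv.py` — strand CV 62.7 cm/s at defaults; doubling the
  diffusivity multiplies CV by 1.4101 (cable theory: √2 ≈ 1.4142).
- `04_build_ventricles.py` — mesh, bull's-eye wall thickness, landmarks.
- `06_cohort_statistics.py` — synthetic cohort, exact Wilcoxon /
  Mann-Whitney / Spearman statistics, derived LV volumes.

A thin CLI wraps the same pipeline
(`cardiotwin generate-geometry | simulate | personalize | measure-cv |
synth-cohort | cohort-stats | bulls-eye | sensitivity`), driven by a YAML
configuration; every run writes a provenance record with the config hash.

## Layout

```
src/cardiotwin/
  params.py, tissue.py      tissue parameters -> conductivity; sensitivity
  ionic/                    ten Tusscher-Panfilov 2006 + pacing protocols
  mesh/                     idealized biventricle, UVC, fibers, AHA, landmarks
  propagation/              strand & FEM monodomain, eikonal, CV calibration
  personalize.py            radius ratio, two-step fit, QRS models
  cohort/                   synthetic cohort, statistics, summaries
  io/, config.py, cli.py    CARP/VTU/tables I/O, run config, CLI
docs/methods.md             model assumptions, numerics, limitations
```
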