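# Methods

## Scope and data model

The package computes, for each subject of a labelled cohort, the standard
clinical FET PET parameters and a grey-level texture panel from a dynamic
PET volume, and evaluates how well single parameters and two-parameter
logistic combinations predict a binary genotype label (IDH-mutant = 1).
Inputs are 4-D activity volumes (NIfTI-1, kBq/mL) with a sidecar frame
schedule; frame timing is never read from NIfTI headers because dynamic
PET timing survives export chains unreliably.  All stages require
identical voxel grids; nothing resamples silently.  Physical quantities
(VOI diameter, PSF width, spacing) are millimetres; grey-level matrices
live on the index grid and ignore voxel anisotropy in direction weights.

## Standard uptake parameters

* **SUV scaling** divides tissue activity (kBq/mL) by injected activity
  per gram of body weight; with MBq and kg this is a voxelwise factor
  `weight_kg / activity_MBq`.
* **Summed image**: duration-weighted mean of frames overlapping
  20–40 min p.i.; on the standard 16-frame schedule (5×1, 5×3, 6×5 min)
  this is the plain mean of four 5-min frames.
* **Reference**: mean SUV in a 30 mm sphere (14.2 mL) whose centre the
  caller supplies; the sphere must fit inside the grid because a clipped
  reference biases the background mean.  Manual contralateral placement is
  not automated (anatomy is out of scope); the synthetic cohort records
  the reference centre per subject.
* **Auto-contour**: threshold at SUV ≥ 1.6 × reference mean, keep the
  26-connected component containing the seed if given, else the largest.
  Inclusion filters: a lesion must exist (criterion "pathological
  uptake") and exceed 100 voxels; excluded subjects are logged, not
  errored.
* **TAC, TTP, slope**: per-frame mean SUV over the fixed tumor mask.  TTP
  is reported at the *mid-time* of the peak frame (mid vs end is a
  convention; mid-time is symmetric), ties resolving to the earliest
  frame.  Slope is the unweighted OLS slope of mean SUV against mid-time
  in hours over frames with mid-time in 20–50 min (indices 10–15 on the
  standard schedule).

## Texture features

The summed image is discretized to G = 64 uniform bins between the
in-mask minimum and maximum (the conventional default of the tooling used
in this field; G and the bounds are config-exposed and recorded, since
features are G-sensitive).  Families:

* **Histogram**: standardized third/fourth moments of the raw in-mask
  values (kurtosis non-excess), entropy (bits) and energy of the G-bin
  histogram.
* **GLCM**: one matrix accumulated over all 13 unique directions at
  Chebyshev distance 1, symmetrized and normalized; pairs crossing the
  mask boundary are skipped.  Accumulating one matrix (rather than
  averaging 13) is deterministic and matches common tool behaviour.
* **GLRLM**: maximal same-level runs per direction, accumulated into one
  matrix; run percentage RP = R/(N·D) with D the number of directions.
* **GLZLM**: zones are 26-connected components of constant level inside
  the mask; features weight zone size s and level g exactly as the
  run-length family weights run length, e.g. SZHGE = (1/Z) Σ n(g,s) g²/s².
* **NGLDM**: the dependence matrix Q(g, d) counts voxels of level g with
  d equal in-mask 26-neighbours (d ∈ 0..26) and is exposed for
  inspection; the three summary features (Coarseness, Contrast, Busyness)
  use the grey-level-difference form — per-level occupancy p_i of voxels
  having at least one in-mask neighbour and summed absolute deviation s_i
  from the neighbourhood mean level — because that is how the named
  feature triple is defined in the field.

The panel has 35 named features.  Analyses in this setting are often
reported as "33 textural parameters" without an enumeration; this package
implements every feature in the abbreviation set it targets and lets the
modeling stage operate on whatever columns are present.

Degenerate cases (constant region → undefined GLCM correlation and NGLDM
features; single voxel → dependence 0) return flagged NaN rather than
raising; flagged features are listed in the per-subject QC log and
dropped by the modeling stage.

## Synthetic cohort generator

The generator emulates the *measurement conditions*, not tumor biology:

* Geometry: one ellipsoidal tumor (mean radius drawn from 8–14 mm,
  per-axis eccentricity ±20%) at a fixed fractional position in a
  48×48×32 grid at 2 mm spacing; the reference sphere sits contralateral.
  An optional central cold core (fractional radius, uptake multiplier)
  can produce ring-like lesions.
* Intratumoral texture: a stationary multiplicative lognormal field
  exp(h·z) with z a unit-variance Gaussian field of ~2-voxel correlation
  length, renormalised to mean 1 over the tumor so TBR targets and
  heterogeneity h are independently controllable.  Defaults: h = 0.35
  (wildtype) vs 0.15 (mutant).  No per-class texture statistics are
  published for this contrast; the direction (wildtype more
  heterogeneous) follows the heterogeneity framing of zone-based features
  and is clearly surfaced in the config.
* Per-class TAC calibration (means ± SD): stand-alone-scanner preset
  wildtype TBR_mean 2.2±0.3, TTP 28.0±9.6 min, slope −0.2±0.5 SUV/h;
  mutant 2.3±0.5, 39.2±7.7, +0.2±0.5.  Hybrid-scanner preset: wildtype
  2.3±0.5, 28.7±12.2, −0.4±0.6; mutant 1.9±0.2, 34.8±6.5, +0.3±0.3.
  TBR draws are truncated at 1.75 so the rendered cohort consists of
  includable lesions, matching how a clinical cohort is assembled.
* Scanner model: Gaussian PSF (6 mm FWHM stand-alone preset, 3 mm
  hybrid), additive Gaussian noise in SUV (default SD 0.05, constant per
  frame — post-reconstruction PET noise at fixed frame duration is
  approximately Gaussian; Poisson emulation is out of scope), mild smooth
  background variation (default 2%), background SUV 1.0, dose 3 MBq/kg
  with body weight ~N(75, 12²) kg clipped to 45–110.
* Reproducibility: one SeedSequence child per subject; the same config
  reproduces volumes and CSVs bit for bit.

### TAC construction and the closure property

The TAC is parameterized directly by its observables (TBR level, TTP,
late slope) rather than by a kinetic compartment model, because only
those observables enter the analysis.  A literal "linear rise to the
peak, then a line with the target slope" does *not* reproduce its own
targets through the measurement: pre-peak rise frames falling inside the
20–50 min regression window drag the fitted slope far from the target
(a curve peaking at 28 min with a −0.3 SUV/h decline fits at roughly
+0.5 SUV/h), and any rising late phase puts the curve maximum in the
final frame regardless of the nominal TTP.  The generator therefore
constructs frame values so that the *measured* quantities equal the
draws exactly:

1. late frames sit on a line whose OLS slope over the window equals the
   drawn slope and whose duration-weighted 20–40 min mean equals the
   drawn TBR target;
2. a perturbation orthogonal to {1, t, sum-window weights} — hence
   neutral to the fitted slope, intercept and TBR mean — raises the frame
   containing the drawn TTP into the strict curve maximum (margin 0.05
   TBR units);
3. pre-window frames rise from zero (or over an early peak, when the
   drawn TTP precedes the window).

One degenerate corner: a non-negative drawn slope with TTP in the final
frame needs no perturbation; with slope exactly zero the late phase is
then flat and the tie-break reports the earliest frame of the plateau.
Draws producing a non-positive curve are redrawn (bounded retries).

## Statistical modeling

* AUC by the rank statistic (ties count ½), evaluated in both directions
  and reported with AUC ≥ 0.5; SE by Hanley–McNeil (no estimator is
  canonical here; this one needs only AUC and class sizes); 95% CI by
  normal approximation clipped to [0, 1]; p two-sided for AUC = 0.5.
* Cut-offs sweep all midpoints of consecutive unique scores plus the two
  classify-all extremes (so accuracy never falls below the majority
  rate), maximizing accuracy with ties broken by higher specificity, then
  lower cut-off.
* Pair models: maximum-likelihood logistic fit on z-scored predictors
  (coefficients reported on the original scale), at most two predictors;
  non-convergence or perfect separation triggers a flagged refit with a
  tiny ridge (1e-6).  Fitted probabilities are scored by the same
  accuracy-maximal cut-off rule; the confusion table at that cut-off
  feeds a two-sided Fisher exact test, Bonferroni-adjusted by the number
  of pair models evaluated (config-exposed).
* Cross-validation: stratified k-fold (the 15/56 class imbalance makes
  unstratified folds degenerate), seeded; the model *and* its cut-off are
  fitted on training folds only; pooled held-out accuracy is reported.
  The pipeline cross-validates the accuracy-ranked best pair; a k that
  exceeds the smaller class size after exclusions is skipped with a NaN.

**Statistical caveat.** The Fisher p of a pair model is computed at a
cut-off *optimized on the same data*, on probabilities from an in-sample
fit.  Such p-values carry selection bias: on label-permuted null cohorts
the measured family-wise rate of a Bonferroni-significant model is
~14–16%, not the nominal ≤5%.  The in-sample accuracies should likewise
be read as optimistic; the cross-validated accuracies are the honest
generalization estimates, which is why the pipeline always reports them
for the best model.

## Problem sizes and numerical choices

The analysis scripts and the acceptance script use the 41/15 cohort on a
48×48×32 grid at 2 mm — large enough for a complete 30 mm reference
sphere, a clearly supra-threshold tumor and a stable texture panel, while
a full simulate–extract–fit cycle stays around ten seconds.  Oracle
equivalence for the texture engine is checked on volumes up to 6³ voxels
with G ≤ 4, where brute-force enumeration is exact and fast.  Tolerances:
texture features match oracles to 1e-10 relative; matrix entries and
Fisher p-values match enumeration exactly (1e-10 absolute); phantom
recovery of TBR/slope is exact by construction and asserted at 1%/0.02
SUV/h.

## What passing tests do and do not show

The synthetic cohort reproduces the *statistical structure* of the
class contrast (slope sign, TTP shift, TBR levels, a texture
heterogeneity difference) under idealised conditions: one ellipsoidal
lesion per subject, stationary texture, Gaussian blur and noise, no
necrosis (unless configured), no motion, no reconstruction artifacts, no
anatomy.  Passing tests therefore validate the *computations* — not the
clinical claim; absolute accuracies on synthetic cohorts depend on the
configured effect sizes and should not be compared with patient-cohort
numbers.

## Known limitations

* No DICOM/ECAT ingestion, no partial-volume correction, no kinetic
  modeling, no automated reference placement.
* Texture values depend on G and the discretization bounds; defaults are
  recorded in outputs but cross-study comparability is limited, as is
  generally true for PET texture analysis.
* The Fisher/Bonferroni evaluation of cut-off-optimized models is
  anticonservative (see the statistical caveat above).
* The heterogeneity contrast between classes is a modeling choice, not a
  published measurement.
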