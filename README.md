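# fetradiomics

Static, dynamic and textural analysis of dynamic O-(2-[¹⁸F]fluoroethyl)-L-
tyrosine (FET) PET for non-invasive prediction of the IDH genotype in
glioma, with a seeded synthetic phantom cohort generator so the whole
pipeline is testable without patient data.

FET is an amino-acid tracer whose uptake is independent of blood–brain-
barrier integrity; its kinetics differ between IDH-mutant and IDH-wildtype
gliomas.  This package implements the full quantitative readout used in
that setting and is aimed at researchers in PET neuro-oncology imaging who
want a tested, scriptable version of the protocol:

* **Standard parameters.** Activity is normalised to the standardized
  uptake value, SUV = C_tissue [kBq/mL] / (A_injected / body weight [g]).
  A summed 20–40 min p.i. image is referenced to a 30 mm spherical VOI in
  normal brain (volume 14.2 mL); the biological tumor volume (BTV) comes
  from 3-D auto-contouring at tumor-to-brain ratio TBR ≥ 1.6, yielding
  TBR_mean and TBR_max.  From the tumor time–activity curve: TTP (minutes
  to the curve maximum) and the late slope (OLS fit over 20–50 min, in
  SUV/h).  Falling curves with early TTP are the wildtype pattern; rising
  curves with late TTP the mutant one.
* **Texture panel.** 35 named features on the masked, 64-level discretized
  summed image: histogram (SkewnessH, KurtosisH, EntropyH, EnergyH), GLCM
  (Homogeneity, Energy, Contrast, Correlation, Entropy, Dissimilarity),
  GLRLM (SRE … RP), NGLDM (Coarseness, Contrast, Busyness) and GLZLM
  (SZE … ZP), e.g. SZHGE = (1/Z) Σ_{g,s} n(g,s)·g²/s² emphasising small
  bright zones.  Matrices accumulate over the 13 unique 3-D directions;
  zones use 26-connectivity.  Every feature is verified against
  independent brute-force oracles in the test suite.
* **Diagnostic modeling.** Per-parameter ROC analysis (AUC with
  Hanley–McNeil SE, accuracy-maximal cut-off), two-parameter logistic
  combinations (never more, to limit complexity), Fisher's exact test with
  Bonferroni correction over the models tested, and stratified 5/10-fold
  cross-validation with pooled held-out accuracy.  Positive class is
  IDH-mutant.
* **Synthetic cohorts.** A forward model of already-reconstructed dynamic
  scans on the 16-frame 0–50 min schedule (5×1, 5×3, 6×5 min): ellipsoidal
  tumors with multiplicative lognormal texture in a brain-like background,
  per-class TAC calibration (TBR level, TTP, slope sign), scanner blur of
  3 or 6 mm FWHM, Gaussian noise, 3 MBq/kg dosing.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
calibrated synthetic cohort (41 wildtype / 15 mutant, 6 mm PSF):

```sh
python analysis/01_simulate_cohort.py     # volumes -> scratch/cohort
python analysis/02_extract_features.py    # -> results/features.csv
python analysis/03_fit_models.py          # -> results/models.csv
python analysis/04_recovery_checks.py     # -> results/validation.json
```

A run with the default seed prints:

```
included 54 subjects (40 wt / 14 mut)
QC: sub-033: EXCLUDED (btv_too_small, btv=95)
QC: sub-044: EXCLUDED (btv_too_small, btv=74)
best single standard parameter: tbr_mean (accuracy 0.80, AUC 0.58)
best combination: ttp_min + EnergyH (accuracy 0.93, Bonferroni p 1.4e-07)
cross-validated accuracy: 5-fold 0.87, 10-fold 0.87
```

Two subjects fail the cohort inclusion rule (pathological uptake must
exceed 100 voxels), mirroring how small lesions drop out of a clinical
cohort.  The best single standard parameter classifies 80% of subjects
correctly at its optimal cut-off; combining a standard parameter with a
texture feature raises in-sample accuracy to 93%, and the stratified
cross-validated accuracies (87%) stay close, i.e. the gain is not pure
overfitting.  The recovery checks confirm that noise-free phantoms return
their target TBR_mean and slope to machine precision and that the
empirical slope AUC matches the closed-form binormal value
Φ(0.7/√0.45) ≈ 0.852.

The same stages are available as a CLI
(`fetradiomics simulate|extract|fit|run-all`) driven by a YAML config, and
as library calls (`generate_cohort`, `extract_cohort_features`,
`run_model_search`, `run_all`).

## Layout

```
src/fetradiomics/   io, synthesis, uptake, texture, modeling, pipeline, cli
analysis/           numbered narrative drivers (simulate -> extract -> fit)
tests/              pytest suite incl. brute-force texture/statistics oracles
docs/methods.md     model, parameters, numerical choices, limitations
```
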