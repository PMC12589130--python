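# bmigap

Normative modeling of body-mass index from voxel-wise gray-matter-volume
(GMV) images, with individualized gap scores (predicted − measured BMI,
bias-corrected), voxel-reliability maps, sparse-PLS clinical associations and
weight-gain outcome analyses — all exercisable end-to-end on synthetic GMV
phantoms with planted, recoverable structure.

## What is in the box

| module | purpose |
| --- | --- |
| `bmigap.synthetic_cohort` | phantom GMV cohorts: planted BMI pattern, partially overlapping disease pattern, per-subject gap, follow-up weights coupled to the gap |
| `bmigap.imaging_io` | NIfTI volumes, boolean voxel masks with a canonical feature ordering, cohort TSV validation |
| `bmigap.cohort_design` | BMI binning (0.5-wide bins), balanced per-bin selection with greedy age matching |
| `bmigap.normative` | leakage-free preprocessing chain (smooth → age residualize → site offset → PCA → min-max scale), repeated nested 5×5/5×5 CV, linear ν-SVR / SVM, ensemble prediction, label-permutation test |
| `bmigap.reliability_maps` | back-projected weight maps, cross-validation-ratio (CVR) maps, exact-binomial sign-consistency maps with BH-FDR, binarization and overlap/Dice statistics |
| `bmigap.bmigap_metric` | gap computation, OLS bias correction (fit on discovery out-of-fold gaps only), group/medication/dosage association tests |
| `bmigap.spls_assoc` | sparse partial least squares (L1-ball projected power iterations, projection deflation), LV permutation tests, bootstrap ratios |
| `bmigap.weight_outcomes` | ΔW tables, +3/+5/+7 % gain subgroups, age/sex/group-stratified gap–ΔW correlations with per-panel FDR, nested-CV weight-gain classifier with gap-feature ablation |
| `bmigap.cli_runner` | staged pipeline (simulate → design → train → predict → gap → maps → spls → outcomes → report) with YAML config, per-stage seeds and a hashed run manifest |

## CLI

```bash
bmigap all --config config.yml --seed 1 --outdir run/
bmigap simulate --outdir run/      # or any single stage
```

A config file is YAML with the fields of `bmigap.cli_runner.RunConfig`
(phantom spec, CV sizes, hyperparameter grids, α levels, SPLS settings).
Every stage writes its outputs plus a `manifest.json` with per-file SHA-256
hashes; re-running the same config reproduces identical hashes.

Cohort tables are TSV with columns `subject_id, site, group (HC/SCZ/CHR/ROD),
split, age, sex (F/M), bmi_measured, weight_t0/t1/t2, panss_total,
age_at_onset, illness_duration, n_hospitalizations, antipsychotic_naive,
antidepressant_naive, weightgain_med (yes/neutral_or_none/unknown),
cpz_equiv, exercise, somatic_history, tobacco`. Images are NIfTI-1
(`.nii`/`.nii.gz`); masks are byte volumes on the same grid; the feature
ordering is ascending linear index in C memory order of the mask volume.

## Conventions

- Voxel→world affines are RAS; voxel indices are 0-based; affine comparisons
  use an absolute tolerance of 1e-4.
- All preprocessing parameters are estimated on training rows only; discovery
  predictions are strictly out-of-fold; the gap bias correction is fit on
  discovery out-of-fold gaps and applied unchanged everywhere else.
- Permutation p-values use the add-one estimator (1 + hits)/(n + 1).
- CVR = mean(w) / (sd(w)/√M) across CV models; zero-variance voxels are
  capped at ±1e6. Sign consistency uses the exact two-sided binomial test at
  p₀ = 0.5 with Benjamini–Hochberg FDR.
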