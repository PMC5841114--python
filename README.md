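# petquant

Whole-body volumetric quantification of FDG-PET for tumour-burden
biomarkers, built for imaging researchers who want a transparent,
testable implementation of threshold-based lesion segmentation and the
survival analysis that follows from it.

## What it does

Recurrent and metastatic disease — the motivating setting is
nasopharyngeal carcinoma after comprehensive therapy — shows up on
FDG-PET as multiple lesions whose *total* metabolic burden predicts
outcome better than any single-lesion measurement. The pipeline:

1. **Segmentation.** Each annotated lesion is grown in 3D
   (6-connected, from its hottest voxel) above one of four SUV
   thresholds:
   - absolute: `Th2.5 = 2.5`
   - relative: `Th20 = 0.20 · SUVmax`, `Th40 = 0.40 · SUVmax`
   - background-relative:
     `Thbgd = SUVbgd + 0.20 · (SUVmax − SUVbgd)`, with `SUVbgd` the
     mean of the maximum SUVs of ten randomly placed background
     regions around the lesion.

   A lesion whose grown region escapes its dilated bounding box has
   merged with background (`LEAKED`); one whose seed is below
   threshold is `EMPTY`; only `DETECTED` lesions count as segmented.

2. **Quantification.** Per lesion: `MTV` (cm³), `SUVmean`, `SUVmax`,
   `TLG = MTV · SUVmean`. Per patient: `WBMTV = Σ MTV`,
   `WBTLG = Σ TLG` over detected lesions.

3. **Cohort statistics.** Detection-rate comparison across the four
   rules (chi-square / Fisher), ROC cutoff selection for WBMTV/WBTLG
   (Youden's J), Kaplan–Meier survival stratified at the cutoff with
   the log-rank test, and a seven-covariate multivariate Cox model
   (age, gender, treatment, lesion count, SUVmax, WBMTV, WBTLG) for
   overall and disease-free survival.

4. **Synthetic data.** A digital-phantom generator (blurred spheres of
   known volume and contrast in uniform background) and a cohort
   simulator whose hazard rises log-linearly with WBTLG, so every
   stage is validated against known ground truth. See
   `docs/methods.md` for the models and their limits.

## Worked example

The numbered scripts under `analysis/` run the full study; each writes
its tables to `results/`. For example, the prognostic workflow on a
simulated 221-patient cohort:

```sh
$ python analysis/03_prognosis.py
simulated cohort: 221 patients, 91 deaths, median WBTLG 50.8 (mean 99.0 - right-skewed)
ROC: AUC 0.540, Youden cutoff 123.34 (sens 0.29, spec 0.81)
5-year OS: 72.3% (WBTLG < cutoff, n=170) vs 71.8% (>= cutoff, n=51); log-rank chi2 0.1, p = 0.7
Cox OS: WBTLG HR 1.0033 [1.0012, 1.0054], p = 0.00224
Cox DFS: WBTLG HR 1.0069 [1.0034, 1.0105], p = 0.00013
```

Reading this: the simulated per-unit WBTLG effect is small
(true log-hazard 0.003, so HR ≈ 1.003 per unit — recovered by the Cox
fit with a tight CI), which is exactly the regime where a multivariate
model finds the biomarker while a single median-type split shows
little separation at n = 221. The detection-rate study
(`analysis/02_detection_rates.py`) reproduces the published
accounting — 378/576 = 65.6% (Th2.5), 462/576 = 80.2% (Th20),
412/576 = 71.5% (Th40), 521/576 = 90.4% (Thbgd) — and shows the same
qualitative ranking emerge from the segmentation code on a phantom:
the background-relative rule segments every lesion while the absolute
rule is blind below SUV 2.5 and the fractional rules leak on
low-contrast lesions.

There is also a CLI for running the stages on files:

```sh
petquant phantom --config phantom.yaml --seed 1 --out phantom_out/
petquant segment --image phantom_out/phantom.nii.gz \
                 --annotations phantom_out/annotations.json --out seg_out/
petquant prognosis --cohort cohort.csv --biomarker wbtlg --out prog_out/
```

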