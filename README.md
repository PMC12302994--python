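# skinraman

Raman-spectral classification and biochemical analysis of nonmelanoma
skin-cancer structures.

Confocal Raman microspectroscopy measures a vibrational "fingerprint" of
tissue at a point; acquired under 3-D image guidance inside surgical
specimens, such spectra can be labeled by the structure they probe:
healthy epidermis (EPI-H), epidermis above basal-cell-carcinoma lobules
(EPI-T), healthy dermis (DER-H), BCC tumor lobules (LOB-T) and
squamous-cell-carcinoma tumor (TUM-T). This package implements, as a
tested and reusable pipeline, the analysis such a study needs:

* **synthetic cohorts** (`skinraman.synth`) — spectra on a 0–3050 cm⁻¹
  axis with class-specific biochemical bands, fluorescence baselines,
  the CaF₂ window line at 321 cm⁻¹, dark background, per-patient random
  effects and triplicate noise averaging, so every downstream stage is
  testable without clinical data;
* **preprocessing** (`skinraman.preprocess`) — per-range chain on
  800–1350, 1350–1750 and 2800–3000 cm⁻¹: 50 cm⁻¹ margin extension,
  asymmetric polynomial baseline correction (orders 5/5/1, tolerance
  0.01), margin removal, SNV normalization, Savitzky–Golay smoothing
  (order 2, window 13), concatenation into a 1153-channel feature vector;
* **classifiers** (`skinraman.models`) — a 1-D CNN (convolutions with
  kernels 7/3/3, stride 2, features 16/32/64, group normalization with 4
  groups; fully connected 256/64/n_classes with batch normalization),
  implemented in pure numpy, plus gradient-boosted trees (100 trees,
  depth 5), 10-NN, an MLP (32/16) and an RBF SVM;
* **evaluation** (`skinraman.evaluation`) — five-fold cross-validation
  stratified by label with patients grouped (no patient ever appears in
  both training and validation), one-vs-rest ROC AUC with macro
  averaging, multiclass and thresholded binary confusion matrices with
  recall/sensitivity/specificity/accuracy/precision;
* **occlusion attention** (`skinraman.attention`) — zero out sliding
  windows (size 13, stride 5), measure the change in the true-class
  probability, project to channels, average over out-of-fold samples,
  min–max normalize; fold-to-fold stability as mean pairwise cosine;
* **band deconvolution** (`skinraman.biochem`) — bounded Gaussian
  nonlinear least squares of the DNA region (1025–1165 cm⁻¹) and the
  high-wavenumber CH region; band areas (e.g. AUC1089, AUC2931), percent
  band differences, and the lipid index
  (AUC₂₈₄₀₋₂₈₇₀ + AUC₂₈₇₀₋₂₈₉₀) / (AUC₂₉₂₀₋₂₉₄₀ + AUC₂₉₄₅₋₂₉₆₅).

## Worked example

```python
import skinraman as sr
from skinraman.pipeline import class_band_analysis

# clinical-shape synthetic cohort: 247 BCC + 85 SCC patients, 1382 spectra
cohort = sr.generate_cohort(sr.CohortConfig(seed=11), sr.default_profiles())
report = class_band_analysis(cohort)
print(report.summary())
```

```
   class  AUC1089(fit)  AUC1089(rng)   AUC2931  lipid idx
   DER-H        5.3545        4.1329   21.2763     0.7952
   EPI-H        5.7360        4.4402   32.0041     1.1748
   EPI-T        6.8272        5.2651   31.7834     1.1079
   LOB-T        9.7235        7.4710   21.2514     0.6776
   TUM-T        5.8199        4.5047   46.6915     0.9125
DNA band excess, LOB-T vs EPI-H: +69.5% (component) / +68.3% (range integral)
keratin band excess, TUM-T vs EPI-H: +45.9%
```

The generator plants a 1.7× DNA-backbone band (1089 cm⁻¹) in tumor
lobules and a 1.44× keratin band (2930 cm⁻¹) in SCC epidermis; the
deconvolution recovers those excesses (+69.5 % and +45.9 % here — the
small biases come from overlapping-band fits, not noise). The lipid
index is highest in the epidermal classes and lowest in tumor lobules
and dermis, as planted.

Classification and attribution run the same way:

```python
processed = sr.preprocess_dataset(cohort)              # (1382, 1153) features
cv = sr.cross_validate(processed, "cnn", classes=4, seed=11)
print(cv.report.summary())                             # AUCs + confusion matrix
maps, consistency = sr.compute_attention(cv, processed.features,
                                         channel_map=processed.channel_map)
```

On a small planted cohort the 4-class CNN report looks like:

```
classes: EPI-H, EPI-T, DER-H, LOB-T
spectra evaluated: 32 (excluded: 16)
macro one-vs-rest AUC: 1.0000
...
confusion matrix (rows = truth, count (row proportion)):
                    EPI-H            EPI-T            DER-H            LOB-T
   EPI-H      8 (100.0%)      0 (  0.0%)      0 (  0.0%)      0 (  0.0%)
   EPI-T      4 ( 50.0%)      4 ( 50.0%)      0 (  0.0%)      0 (  0.0%)
   DER-H      0 (  0.0%)      0 (  0.0%)      8 (100.0%)      0 (  0.0%)
   LOB-T      0 (  0.0%)      0 (  0.0%)      0 (  0.0%)      8 (100.0%)
```

(The 16 excluded spectra are the SCC acquisitions, which the 4-class
BCC-only setup drops; synthetic classes are far better separated than
clinical tissue, so near-perfect AUCs here say nothing about clinical
performance.)

A `skinraman` CLI wraps the stages
(`simulate`, `preprocess`, `train`, `evaluate`, `attention`, `biochem`,
`run`); e.g. `skinraman run --out report/ --seed 11` executes everything
and writes plain-text artifacts, each embedding the configuration hash.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch — cohort
simulation, preprocessing, cross-validated CNN evaluation in both class
setups, occlusion attention and the biochemical band analysis — writing
the pipeline artifacts next to the JSON output.

See `docs/methods.md` for the models, defaults, numerical choices and
known limitations.
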