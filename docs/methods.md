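# Methods

`skinraman` implements a complete desk-scale replica of a clinical Raman
workflow for nonmelanoma skin cancer: confocal Raman spectra are acquired
at image-guided points inside surgical specimens, labeled by tissue
structure, classified with a small 1-D CNN (and four classical baselines)
under patient-grouped cross-validation, attributed with occlusion
attention, and analyzed biochemically by Gaussian band deconvolution.
Because no clinical spectra are distributed, every stage is validated on a
synthetic cohort whose statistical structure matches what the analysis
assumes. This note records the models, the defaults and why, and what a
green test does and does not establish.

## The synthetic cohort

A spectrum is simulated as

```
I(w) = g_p * [ B(w) + Σ_k A_k f_k(w; c_k, FWHM_k) + CaF2(w) ] + s_p + D(w) + ε(w)
```

* `B(w)` — a smooth polynomial fluorescence background in `w/3000`,
  identical across classes (fluorescence is treated as non-informative);
* `f_k` — Gaussian (default) or Lorentzian bands from a per-class band
  library; all FWHM ≥ 11 cm⁻¹, the spectrometer's optical resolution.
  Real Raman lines are Voigt-like; Gaussian shapes suffice to exercise
  every downstream stage;
* `CaF2(w)` — the single calcium-fluoride sample-window line at
  321 cm⁻¹, identical across classes (a nuisance feature);
* `g_p, s_p` — per-patient multiplicative gain (log-normal, log-sd 0.15)
  and additive offset (sd 0.05), drawn once per patient. The gain/offset
  pair is exactly the family of transforms that SNV normalization should
  cancel, which makes the preprocessing chain testable;
* `D(w)` — a smooth low-amplitude dark background (laser-off detector
  signal), one per cohort, subtracted during preprocessing;
* `ε` — additive homoscedastic Gaussian noise, sd 0.03 per replicate
  against band amplitudes of 0.3–2 (single-band SNR roughly 10–60);
  three replicates are averaged per acquisition, as in the acquisition
  protocol. Poisson shot noise, cosmic-ray spikes and detector etaloning
  are deliberately not modeled.

The default class profiles plant the study's reported biochemistry as
ground truth: the DNA O–P–O band at 1089 cm⁻¹ with amplitude ×1.7 in
BCC tumor lobules (LOB-T) relative to healthy epidermis (a +70% band
area); the keratin CH₃ band at 2930 cm⁻¹ ×1.44 in SCC tumor epidermis
(TUM-T, +44%); a collagen-rich dermis; and lipid bands (2855/2880 cm⁻¹)
stronger in epidermal classes than in tumor lobules and dermis, so the
lipid index ordering is epidermis > {LOB-T, DER-H}. Other band
amplitudes were set once to plausible relative intensities for skin and
are not revisited. With `effects=False` all five classes share one band
set, giving an exchangeable null cohort.

The default cohort shape matches the clinical study: 247 BCC and 85 SCC
patients; 253/364/236/216 spectra for EPI-T/LOB-T/EPI-H/DER-H on BCC and
219/94 for TUM-T/EPI-H on SCC (1382 spectra, 332 patients). A patient
belongs to exactly one lesion type, and patient effects are drawn once
per patient.

**Grid.** The channel spacing of the spectrometer output is not public;
we default to 1 cm⁻¹ steps. The axis runs 0–3050 cm⁻¹: the nominal
acquisition span is 0–3000, but the preprocessing margin extension needs
coverage to 3050 for the 2800–3000 range, and we chose strict margin
checking (an explicit error on insufficient coverage) over silent
clipping. On this grid the three canonical ranges contribute
551 + 401 + 201 = 1153 feature channels (closed intervals; 1350 cm⁻¹
belongs to both fingerprint ranges).

What a green test establishes: that the *pipeline machinery* —
preprocessing algebra, leakage-free cross-validation, attribution
localization, deconvolution recovery — behaves correctly on data with
known ground truth. It does not establish clinical performance; the
headline clinical metrics require the undeposited patient spectra.

## Preprocessing

Per range (800–1350 order 5, 1350–1750 order 5, 2800–3000 order 1; all
margins 50 cm⁻¹): margin extension → asymmetric polynomial baseline
correction → margin removal → SNV → Savitzky–Golay (order 2, window 13);
ranges are then concatenated. Choices the sources leave open:

* **Baseline cost.** "Asymmetric quadratic with tolerance 0.01" is
  implemented as iteratively reweighted least squares with a truncated
  asymmetric quadratic cost: points whose residual above the current
  baseline exceeds 0.01 × the segment's intensity span get zero weight
  (they are peaks); points on or below keep weight 1. Iteration stops on
  stable weights or a relative baseline change < 1e-6 (max 100
  iterations); non-convergence warns with the residual norm and returns
  the best fit.
* **SNV** uses the sample (n−1) standard deviation, the chemometrics
  convention; a flag switches to population sd.
* **Savitzky–Golay edges** use polynomial-fit extrapolation inside the
  terminal windows (`scipy` `mode="interp"`), since the margins were
  already trimmed and edge channels are real data. A consequence worth
  recording: the post-smoothing per-range mean is zero only to ~1e-4 on
  noisy spectra (SNV's exact zero mean is perturbed by the edge
  handling); tests assert the exact 0/1 moments on the SNV output itself.
* **Intervals** are closed `[lo, hi]` on the grid, which makes the
  551/401/201 channel counts deterministic.
* **Order of operations.** Dark subtraction is applied before replicate
  averaging (one dark per specimen precedes its acquisitions); for
  channelwise linear operations the order is immaterial to the result.

## Classifiers

The 1-D CNN: three valid (unpadded) convolutions (kernels 7/3/3, stride
2, features 16/32/64), each with 4-group group normalization and ReLU;
flatten; three fully connected layers (256/64/n_classes) with batch
normalization then ReLU on the hidden layers, in that listed order.
Valid convolution was chosen over "same" padding (output lengths
574/286/142 for a 1153-channel input); the source architecture statement
does not fix padding. PyTorch is not a dependency: the network is ~300
lines of numpy (im2col convolutions, analytic normalization gradients,
Adam), which keeps the training loop bit-deterministic under a seed.

Training regimen (unstated in the sources, so chosen as the standard
recipe for small 1-D CNNs and fully exposed in `TrainingConfig`):
multiclass cross-entropy, Adam at 1e-3, 100 epochs, batch 32, no class
reweighting. Baselines: gradient-boosted trees (100 estimators, depth 5;
scikit-learn's histogram GBM stands in for XGBoost, which is not in the
environment), 10-NN with Euclidean distance, an MLP with hidden layers
32/16, and an RBF-kernel SVM with probability outputs.

## Evaluation

Five-fold cross-validation, stratified by label with patients grouped:
each patient is represented by its majority target label (ties broken by
label order) and patients are split by stratified k-fold; every spectrum
inherits its patient's fold, and the train/validation patient sets are
asserted disjoint in every fold. Out-of-fold scores (never refit-on-all)
feed both the report and the attention analysis. One-vs-rest ROC AUC per
class (ties half credit) is macro-averaged; multiclass confusion matrices
use the argmax class with row-wise normalization; per-class binary
matrices use a 0.5 threshold. "Recall" and "sensitivity" are synonymous
for the positive class; both are emitted, equal, rather than guessing a
different intent for one of them.

## Occlusion attention

Windows of 13 channels at stride 5 are zeroed and the absolute change in
the true-class probability is recorded ("variation"); measuring on the
predicted-class probability or the whole score vector (L1) is available
as an option, since the sources do not fix the quantity. Window
variations are projected to channels (mean over covering windows;
trailing uncovered channels inherit the nearest window), averaged per
class over all out-of-fold samples of all folds, and min–max normalized
— normalization after averaging, matching the stated sentence order;
constant vectors normalize to all zeros. Occlusion operates on the
concatenated feature vector; windows straddling a range boundary are
flagged in the output. Fold consistency is the mean pairwise cosine
similarity between per-fold class-average vectors.

A caveat discovered on the single-discriminative-band cohort: SNV couples
a planted band difference into *every* channel of its range (the
normalization rescales the whole segment), so a model may legitimately
read reference bands when classifying the class whose band is *not*
elevated. The elevated class's map and the overall (all-sample) map
localize at the planted band; the reference class's map need not. The
localization tests are therefore asserted on those two maps.

## Band deconvolution

Nonlinear least squares (trust-region reflective, bounded) over sums of
Gaussians; "width" means FWHM (a toggle accepts sigma). Centers are
bounded to ±10 cm⁻¹ of their initial guesses and widths to [5, 60]
cm⁻¹, which stabilizes the five-component high-wavenumber fit. Reduced
chi-square = RSS / ((n − 3m) · σ²) with σ² estimated from a signal-free
sub-region when one is supplied (unit weights otherwise).
Deconvolution operates on baseline-corrected but **not** SNV-normalized
class-average spectra: area ratios are scale-invariant, but SNV's
per-range shift would distort them. The DNA region (1025–1165 cm⁻¹) is
fitted with three components initialized at 1065/1089/1126 cm⁻¹;
AUC1089 is reported both as the fitted component's closed-form area and
as a trapezoid integral over 1089 ± 9 cm⁻¹, since the sources do not say
which was used. The high-wavenumber region uses the four named
components (2855/30, 2880/20, 2930/20, 2955/20 center/FWHM) plus one
filler near 2900 cm⁻¹. On the default full-size cohort this recovers the
planted +70% DNA excess to within a few percentage points and the +44%
keratin excess within ~2 points (deconvolution overlap, not noise, sets
the bias).

## Reproducibility and limitations

Every stage draws randomness from `numpy.random.Generator` seeded from
the run configuration; two runs of the full pipeline with one seed
produce byte-identical artifacts (hashes compared in the tests). All
artifacts are plain text and embed the configuration hash.

Known limitations: the synthetic classes are far better separated than
clinical tissue (classification AUCs near 1 on planted cohorts say
nothing about clinical AUC); band libraries are Gaussian approximations;
no wavenumber/intensity calibration, despiking, or shot noise; the
numpy CNN trains on CPU only and is sized for hundreds, not millions, of
spectra.
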