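# Methods

This note records the models, conventions, parameter choices and known
limitations of the package, in the order data flows through it.

## RF simulation model

Each scan line is synthesized in the frequency domain as

    Y(f) = P(f) · (f/MHz)² · Σₖ aₖ · exp(−i2πf·2zₖ/c) · G(f; aₖ_eff) · A(f; zₖ)

where `P(f)` is the analytic spectrum of a Gaussian-enveloped 7 MHz pulse
(−6 dB fractional bandwidth 5/7, so the usable band covers 4–9 MHz),
`(f/MHz)²` is the Rayleigh amplitude dependence of sub-wavelength
scatterers, `G = exp(−0.827(ka/2)²/2)` the spherical-Gaussian form factor
in amplitude, and `A = 10^(−4αfz/20)` the attenuation term. Scatterer
delays are continuous (no sample-grid quantization), which is what makes
sub-bin spacing recovery testable. There is no lateral point-spread
coupling: a scatterer contributes only to its nearest line. This
deliberately reduced model reproduces exactly the statistics the
estimators consume — comb spectra from quasi-regular spacing,
density-proportional incoherent power, form-factor roll-off, and
depth-cumulative attenuation — and none of the wave-propagation effects
(diffraction, multiple scattering, aberration) of real tissue. Passing
tests therefore validate estimator correctness under the stated model,
not robustness to full acoustic physics.

**Attenuation convention.** One number, used everywhere: echoes from
depth `z` lose `4·α·f_MHz·z_cm` dB of *power-spectrum* level relative to
the lossless reference (α in dB/cm/MHz). The simulator applies it, the
spectral-difference estimator inverts it (ACE = −slope/(4f)), and the
correction re-adds it. Recovery tests close this loop.

**Acquisition defaults** (`AcquisitionSpec`): 40 MHz sampling, 16-bit
quantization at container-write time, 7 MHz center frequency, 4–9 MHz
analysis band, c = 1540 m/s (soft-tissue convention), 0.2 mm line pitch.

**Reference phantom**: ≥5 frames of dense diffuse scatterers
(4·10⁸ /m², 10 µm diameter — spectrally flat in band), zero attenuation.
The reference spectrum is the linear-power average over all frames and
lateral positions at the matched depth window, which suppresses speckle
variance in the calibration. Because the phantom's backscatter is
Rayleigh (∝ f⁴), normalization cancels f⁴; the form-factor fit restores
it (+40·log₁₀ f) before fitting the model with the f⁴ term, which is
algebraically identical to fitting the form factor directly on the
normalized spectrum.

## Synthetic cohorts

`CohortSpec` defaults define the emulated study: 28 recurrence (R) / 55
non-recurrence (NR) patients; 3–7 tumor-slice frames each (the number of
1 cm-interval slices through a tumor is not fixed in practice, so it is a
parameter); elliptical ROI in a 16 mm × 6.4 mm field. Tissue is diffuse
speckle (2·10⁸ scatterers/m², 80 µm effective diameter) plus a jittered
quasi-periodic lattice (0.45 mm spacing, amplitude 2.5× speckle)
representing the quasi-regular lobular architecture that makes SAS
estimable in breast tissue; without it SAS is invalid almost everywhere
and the patient-level SAS average would be undefined.

Class separation is injected **only** through heterogeneity: the R class
gets a smooth random patch field (1.5 mm correlation length) modulating
scatterer density by up to 3×, normalized to unit mean so class means of
backscatter are untouched; the NR class is uniform. Consequently the
discriminating features are texture and texture-derivative statistics,
not first-order means — mirroring the premise that intratumoral
heterogeneity carries the prognostic signal.

Outcomes: per-class exponential event times — recurrence hazard
0.029/month for R (median ≈ 24 months) vs 0.0045 for NR; death hazard
0.005 vs 0.0027 (5-year OS ≈ 74% / 85%) — with RFS = min(recurrence,
death) (death without recurrence counts as an RFS event, the
conventional composite), OS = death, and administrative censoring at 69
months (the emulated median follow-up).

## Spectral estimation

* Sub-ROI grid: 2 mm × 2 mm windows, 94% overlap default (stride
  = window × (1 − overlap), floored at one sample/line); windows whose
  footprint touches the ROI complement are excluded. Several studies in
  the tests use 50–85% overlap purely to keep grids small; overlap does
  not change any estimator.
* Per-line Hann taper, periodogram, line average; FFT zero-padded 4×
  (e.g. 104-sample windows → nfft 512). The intrinsic resolution remains
  fs/window-length; zero-padding only smooths interpolation.
* ACE per frame (not per window): depth regression needs many depths, so
  row-averaged normalized spectra are regressed against window-center
  depth; negative estimates clamp to 0.
* MBF evaluated at the band midpoint, 6.5 MHz.
* SAS: the linear normalized spectrum is flattened by a ~1 MHz
  moving-average envelope, mean-removed, autocorrelated over frequency
  lags; the dominant local maximum in the lag window corresponding to
  spacings 0.1–2 mm (and ≤ 75% of the band width) is refined by parabolic
  interpolation. Validity requires the normalized autocorrelation peak
  ≥ 0.45, a threshold calibrated on the generator so that pure lattices
  validate ≥ 90% of windows while fully diffuse media invalidate the
  majority; invalid cells are excluded via the map's validity mask, never
  imputed.
* ASD/AAC: log-spaced 60-point grid search over diameters 1–300 µm with
  one linear refinement; the amplitude offset is closed-form per
  candidate. A best-fit diameter pinned at a search bound flags the cell
  invalid (no measurable roll-off in band).

## Texture and texture derivatives

GLCM with Ng = 16 gray levels (uniform min–max binning of valid cells;
constant maps collapse to one level), displacement 1, symmetric pair
counting, normalized to unit sum, features averaged over 0°/45°/90°/135°.
Pairs touching invalid cells are skipped — this is why the GLCM is
implemented in-package rather than via `skimage.feature.graycomatrix`,
which has no mask support (skimage serves as an independent oracle in the
unmasked tests). Feature definitions: CON = Σ(i−j)²p, COR = covariance
over marginal variance (0 when degenerate), ENE = Σp², HOM = Σp/(1+|i−j|).

Texture maps are regenerated per cell from a 5×5-cell neighborhood
(3×3 in some size-constrained tests), clipped at the lattice border,
reusing the map-global quantization — local windows are too small to
define stable level sets of their own. The derivative pass re-quantizes
each texture map on its own min–max range (scale-free second pass) and
excludes the SS and SAS texture maps, leaving 4 parameters × 4 features
× 4 features = 64 third-order scalars named `PARAM-TEX1-TEX2`.

Patient vectors average each feature over the patient's frames; a frame
where a feature is invalid is dropped from that feature's average only,
and a feature invalid on every frame is an error naming feature and
patient (no silent imputation).

## Statistics, classification, survival

* Univariate: Shapiro-Wilk at α = 0.05 per group routes to the unpaired
  two-sided t-test (both groups normal) or Mann-Whitney (exact for
  tie-free groups ≤ 20, tie-corrected normal approximation otherwise).
  No multiplicity correction — each feature is reported at its raw
  p-value, as is conventional for hypothesis-generating radiomics tables.
  The routed procedure's per-feature type-I rate calibrates to
  0.05 ± 0.02 in the acceptance suite.
* Balanced subsets: every minority (R) patient plus equal-size
  majority draws sliced from a random permutation, union covering the
  majority class (28/55 → two subsets of 56). Forward selection (max 3,
  ties to the earlier catalog column) scores candidate sets by mean
  LOOCV accuracy across subsets; the reported confusion matrix comes from
  LOOCV over the full cohort with the selected features. Standardization
  is fit per training fold — the per-fold-oracle tests pin the absence of
  test-row leakage. KNN uses k = 3 (vote fraction as the AUC score) via
  an exact vectorized LOOCV; SVM-RBF uses C = 1, sklearn's "scale" gamma
  (decision values as scores), refit per fold.
* Survival: product-limit estimator with Greenwood variance, events
  before censorings at tied times; two-group log-rank with the
  hypergeometric variance. Both are implemented directly because the
  pipeline needs Greenwood variances and per-group observed/expected
  counts in its reports; lifelines is the independent oracle in the test
  suite (curves, test statistic and p agree to ~1e-9).

## Problem sizes

Simulation studies use a 22 mm × 6.4 mm field (~18k scatterers per
frame), 512-sample windows for spacing recovery (intrinsic bin
78 kHz), 10–20 seeds per recovery study, 50 seeds for the null-AUC
study, 200 replicates for type-I calibration, and 20 paired seeds for
the two-pool comparison. The acceptance script uses the same designs at
10 seeds per RF study. The end-to-end demo cohort is 12 patients × 3
frames. These sizes give Monte-Carlo standard errors comfortably inside
every stated tolerance.

## Known limitations

* The RF model is 1-D per line: no diffraction, beam profile, or
  speed-of-sound heterogeneity; ACE/ASD recovery under those effects is
  untested.
* SAS follows the spectral-autocorrelation reading of scatterer-spacing
  estimation; cepstral or AR-spectrum variants would be drop-in
  alternatives behind the same interface but are not implemented.
* The classifier protocol's subset count and merge rule ("several
  subsets") is under-determined in the emulated study design; the
  implemented rule (selection averaged over subsets, final LOOCV on the
  full cohort) is one defensible choice and is configurable.
* Whether recurrence-free survival should count death without recurrence
  as an event is convention-dependent; the composite definition is used.
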