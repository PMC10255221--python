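# Methods

This note documents the models, numerical choices and limitations behind
`fishspec`, in the spirit of a package reference manual rather than a
study report. Nothing stated here is an empirical claim beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## The measurement model

Three optical modes observe the same fillet:

| mode | physics | bands | range (nm) | cube geometry |
|---|---|---|---|---|
| FL | fluorescence emission, 365 nm excitation | 60 | 438–718 | 500 × 280 |
| VisNIR | reflectance | 125 | 419–1007 | 500 × 280 |
| SWIR | reflectance | 287 | 842–2532 | 384 × 350 |

A line-scan hypercube is rows × cols × bands. Reflectance cubes carry
white and dark reference frames; calibration is element-wise
(raw − dark)/(white − dark), and exposure scaling is assumed linear in
integration time (the stated basis of the instruments' own
exposure-rescaling practice).

## Synthetic data generator

The generator exists because the real spectra are not deposited. It
emulates the *statistical structure* the analysis relies on, not the
radiometry of any instrument.

**Fluorescence.** Each spectrum is a small linear baseline plus two
Gaussian components: P1 fixed at 452.6 nm (FWHM 55 nm) and P2 redward of
it. With day *d* on the study grid {1, 3, 5, 7, 9, 11}:

- Δλ(d) = 60 − 20·(d − 1)/10 nm — peak separation shrinks linearly by a
  total of 20 nm from day 1 to day 11;
- P1/P2(d) = 0.85 + 0.06·(d − 1) — the height ratio grows linearly,
  crossing unity mid-study.

P2's FWHM is drawn once per species/seed from 103.9–115.9 nm. The day-1
separation of 60 nm, the ratio intercept and the slope are generator
choices (the aging *trends* and the endpoints of the width range are
fixed by the documented calibration behavior; the exact day-1 values are
not documented anywhere and were chosen once to make the study-range
spectra realistic: strongly overlapped peaks that merge into a single
maximum). An optional narrow bump at the blue edge emulates incomplete
rejection of the excitation band; it is off by default.

**Reflectance.** A smooth per-species base curve (sum of random broad
Gaussians mapped into [0.2, 0.8]) plus a day-scaled smooth drift vector
(amplitude ~0.012 per day, free parameters — no quantitative
reflectance-aging trend is documented to calibrate against) plus noise.

**Spatial structure.** Cubes contain an elliptical fillet footprint over
dark background, four region gain factors (head/tail × top/bottom, 0.90
to 1.05), smooth multiplicative pixel texture (SD 5 %, Gaussian-filtered),
and — on request — contiguous 4×4 blocks of saturated pixels covering a
target fraction of the foreground. Saturation is modelled as clipping at
the detector ceiling in blocks because the downstream voxel-rejection
rule operates on pixel groups.

**Noise** is additive, band-independent and relative to the signal
maximum; default SD 1 % (a post-averaging line-scan SNR of ~100). All
randomness flows from one seed through named per-mode substreams, so a
(config, seed) pair reproduces a dataset bit for bit.

**Catabolites.** The nucleotide pathway IMP → inosine → hypoxanthine is
sequential first-order kinetics with rates k₁, k₂ (defaults 0.35 and
0.20 day⁻¹, plausible refrigerated-storage magnitudes); the closed form
is used, with the k₁ = k₂ limit handled by k₁t·e^(−k₁t). Components sum
to the initial IMP at every time (closed pathway); the test suite checks
the closed form against a Runge–Kutta integration.

**What passing tests do not show.** The generator's class signal is
low-rank and fairly clean; real fillets add biological covariance
structure, instrument drift, and cross-device misregistration. Perfect
synthetic classification accuracies therefore validate the *machinery*
(no leakage, correct metrics, working fusion), not field performance.

## Preprocessing

Order is fixed and logged: calibrate → exposure-scale → mask → voxelize
→ outlier flagging → optional pretreatment.

- **Mask**: threshold on a high-contrast reference band (middle band by
  default) at a configurable fraction (default 0.2) of the image's
  intensity range, keeping the largest connected component. The method
  is parameter-light and reproducible; no construction method is
  otherwise prescribed.
- **Voxelization**: mean spectrum over each complete 10×10 tile with at
  least 50 % of pixels in-mask; incomplete edge tiles are dropped so
  every voxel has comparable support.
- **Outlier rule**: per-band mean and SD over *all in-mask pixels* (the
  "entire fillet"); a voxel is excluded when at any band strictly more
  than 10 % of its member pixels lie beyond 2 SD. The strict inequality
  matters: a voxel with exactly 10 % outlying pixels is kept. Statistics
  are computed per cube (per acquisition), which is an assumption — a
  pooled-across-days variant would differ.
- **Pretreatments**: SNV divides by the *sample* SD (ddof = 1), so
  (1, 2, 3) → (−1, 0, 1); Savitzky–Golay smoothing reproduces
  polynomials up to its `poly_order` exactly. Classification consumes
  calibrated spectra without SNV by default; SNV is a switch.

## Chemometrics

**PCA.** `pca_fit(..., pretreat=True)` standardizes the band columns
(unit sample variance) before eigendecomposition — PCA of the
correlation matrix. This is the setting in which the eigenvalue > 1
retention rule is meaningful: a retained component must explain more
variance than any single original variable. (Row-wise SNV, a different
operation sometimes conflated with this, remains available in
preprocessing.) Component signs are fixed by making each component's
largest-magnitude loading positive. `%variation_i = λ_i/Σλ` always sums
to one. The scree rule returns the position of the largest second
difference of the descending eigenvalue sequence.

**SOM.** A rectangular Kohonen grid (default 5×5; a hexagonal topology
would change little and complicates distance bookkeeping) trained
online with a Gaussian neighborhood; learning rate and radius decay
linearly. Initialization and presentation order are seeded, so training
is deterministic. Assignments are nearest-codebook in Euclidean
distance. Hierarchical clustering of the codebook uses Ward linkage
(compact spectral classes; configurable), default four classes —
matching the four canonical fluorescence shapes (two-peak, major
shoulder, minor shoulder, single peak). No automatic exclusion of
anomalous spectra is performed.

**Two-peak deconvolution.** The estimation problem is harder than it
looks: at study-range separations (Δλ 40–60 nm) with P2 roughly twice
P1's width, the two Gaussians merge into a *single* local maximum, and a
fully free six-parameter fit is nearly unidentifiable — a numerical
Cramér–Rao computation at SNR 50 puts the separation uncertainty at
3.5–12.7 nm, regardless of optimizer. The implementation therefore:

1. subtracts a linear baseline fitted through the lowest-decile
   (off-peak) intensities;
2. fits a single Gaussian at the tallest maximum; a second local
   maximum, or a single-Gaussian residual above 2 % of the peak height,
   is taken as evidence of a subsidiary component;
3. localizes both centers with the FWHMs *fixed* at prior values
   (55 nm for P1; 109.9 nm, the midpoint of the documented
   103.9–115.9 nm range, for P2), multistarting over ten candidate P2
   positions and keeping the best sum of squares;
4. refines all eight parameters (two Gaussians plus linear baseline)
   with the widths ridge-penalized toward the priors (prior SDs 2.4 and
   1.9 nm FWHM), the penalty weighted by a robust noise estimate from
   second differences — so the fit is exact in the noise-free limit and
   does not wander along the width/separation degeneracy when noise is
   present.

If no second component is detected, `p2_resolved=False`: P2's position
is reported as the inflexion point of P1's red flank and a
`delta_lambda_error` of two band spacings is ascribed. Failed fits raise
after perturbed restarts rather than returning silently.

**Freshness indices.** K = (Ino + Hx)/(IMP + Ino + Hx) and
H = Hx/(IMP + Ino + Hx), the standard additive forms. (The source
formula for these indices is printed with multiplication signs between
the catabolite terms, which conflicts with the well-known simplified
K-value it cites; the additive form is implemented and the discrepancy
flagged here rather than silently resolved.) Both are non-decreasing
along the kinetic flow.

**Day prediction.** A calibration curve maps study days to a feature
(Δλ or P1/P2) measured on a calibration fillet; a query value predicts
the nearest calibration day, ties to the earlier day (the conservative
freshness claim), out-of-range values clamp to the endpoints.

**Goodness of fit.** The Hit Quality Index χ = Σ|xᵢ − yᵢ| on
caller-scaled spectra; lower is better, zero iff identical.

## Classification and fusion

Model defaults are pinned in `MODEL_DEFAULTS` (the only deliberate
non-default is logistic regression's iteration cap of 1000). The
train/test split is stratified by day class (plain random splitting
risks empty classes at small n). The stacking ensemble fits LR, RF and
KNN on the training spectra, appends their predicted labels (as
integers — predictions, not probabilities) to the original feature
block, and trains an LDA meta-model on the augmented matrix; prediction
applies the same augmentation, so the fitted meta-feature width is
bands + 3. The meta-model variant trained on predictions alone is known
to be weaker and is exercised only as a test baseline. Any
cross-validation of the stacker refits base models within each fold.

Fusion is decision-level only: per test unit, the majority label among
the three modes wins; a three-way split falls to SWIR (the mode that
consistently scores highest alone). No cross-mode feature concatenation
is performed. In synthetic studies the per-mode tables are split with a
shared seed and identical ordering, so test units are index-aligned and
voxel-level fusion compares co-located voxels; for real two-instrument
data, where voxels do not co-locate across devices, predictions should
first be collapsed to fillet-day verdicts (`aggregate_to_fillet`, modal
vote, ties to the earliest day) and fused at that level.

The repeated-measurement booster is the exact binomial tail
Σ_{k>n/2} C(n,k) p^k (1−p)^{n−k} (odd n); it boosts any p > ½ and is
checked in the tests against exhaustive outcome enumeration.

## Problem sizes and determinism

Test and acceptance runs use deliberately small study sizes — two
fillets, six days, 15–60 voxels per fillet-day, cubes of order 10⁴
pixels — which exercise every code path of the full-geometry cubes
(500 × 280 × 125 and 384 × 350 × 287 remain the defaults for
`simulate_hypercube`). The whole suite runs in well under a minute;
`scripts/acceptance.py` in seconds. Every stochastic step (generator,
splits, SOM, RF/LR seeds) is driven by explicit seeds; reports and JSON
outputs are byte-reproducible for a fixed (config, seed).

## Known limitations

- The generator's reflectance-aging drift magnitudes are free
  parameters; nothing calibrates them to real fish tissue.
- Gaussian peak shapes are an idealization; real fluorescence bands are
  asymmetric, and the width priors in the deconvolution would need
  re-estimation for a different instrument or fluorophore system.
- No geometric registration between instruments is attempted; fusion
  relies on index alignment (synthetic) or fillet-day aggregation
  (real data).
- QDA on near-degenerate classes can fail on singular within-class
  covariance; the error suggests regularization rather than silently
  shrinking.
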