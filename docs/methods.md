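# Methods

## Problem

A hematoma's optical signature evolves as extravasated blood degrades:
hemoglobin (Soret absorption near 415–430 nm, Q-bands near 540/578 nm)
dominates in the first days, bilirubin (≈460 nm) accumulates and then fades,
and the overall contrast against surrounding skin decays toward resolution.
Given a visible/near-infrared hyperspectral cube of the lesion, the task is
to regress the hematoma age in days.  The package implements the full
analysis: radiometric normalization, lesion-centered patch extraction, a
spectral–spatial CNN compared against a spectral-only Lasso baseline under
leave-one-subject-out (LOSO) cross-validation, and a consensus
band-importance procedure that selects a reduced acquisition band set.

## Models

**Lasso baseline.**  Every patch is collapsed to its per-band mean spectrum;
an L1-regularized linear model maps the spectrum to age.  The penalty is
chosen by internal cross-validation over a 50-point logarithmic grid
anchored at the smallest penalty that zeroes all coefficients; CV folds are
grouped by subject so penalty selection cannot leak subjects.  The nonzero
coefficients act as a wavelength selector.  Because the patch is averaged,
this model cannot see spatial texture.

**Spectral–spatial CNN.**  A two-stage architecture:

1. *Spectral encoder*, applied independently to every pixel spectrum with
   shared weights (pixels are folded into the batch dimension — a
   mathematically identical restatement): Conv1D k=7 → 128, k=5 → 64,
   k=3 → 32 channels (each conv followed by ReLU then BatchNorm), adaptive
   average pooling of the spectral axis to length 16, then an average over
   those 16 positions, giving one 32-vector per pixel.  Pooling to 16 and
   then averaging equals a direct average up to bin weighting when the band
   count is not divisible by 16; both readings are implemented behind the
   `spectral_average` config flag, with "pool-then-mean" the default.
2. *Spatial stage* on the resulting embedding map: Conv2D 3×3 → 64, 2×2 max
   pool, Conv2D 3×3 → 128, 2×2 max pool, adaptive average pooling to 4×4,
   flatten (2048), Linear → 256 → 1, with dropout 0.3 in the head.

BatchNorm is placed *after* the activation (conv → ReLU → BN) — a fixed
design choice of this architecture; conv → BN → ReLU is the more common
ordering but not the one used here.  The same architecture family is reused for every
spectral configuration; only the input band count changes, and the adaptive
pools keep the head width independent of it.

The network, its exact backward pass (including gradients with respect to
the *input*, needed for saliency), and the Adam optimizer are implemented
directly on numpy, with single-thread compiled kernels (numba) for the hot
per-pixel 1-D convolution and normalization reductions, and a
BLAS-accumulation reference path used for verification.  Every layer's
backward pass is checked against central finite differences in float64.

**Training protocol.**  Adam (lr 1e-3, batch 32, weight decay 1e-5) for up
to 100 epochs with random horizontal/vertical flip augmentation and early
stopping when validation MAE fails to improve by 0.01 days for 25
consecutive epochs; the best-epoch parameters (including BatchNorm running
statistics) are restored.  The optimization loss is mean squared error —
RMSE is reported alongside MAE and MSE is the conventional regression
default — while early stopping monitors MAE in days.

Three wrapper-level choices matter for small-cohort training and were
selected on *validation* MAE (mirroring a tuning-split protocol; the
held-out test subjects were never consulted):

* **Target standardization.**  Ages are standardized for optimization and
  predictions mapped back to days.  With raw ages, the zero-initialized
  output head spends most of the epoch budget moving its bias to the mean
  age (~9 days).
* **Per-band ratio input normalization.**  Each band of a patch is divided
  by its own spatial mean (minus one) before per-band standardization.
  Under a multiplicative skin model this cancels the subject's baseline —
  skin brightness, melanin, illumination — exactly and per band; without
  it the model generalizes poorly to unseen subjects.  A global per-sample
  normalization (SNV) also fixes generalization but its scale factor
  depends on the lesion contrast, which smears age information into
  physically uninformative bands and corrupts band attribution; the
  per-band form mixes no wavelengths, so bands without lesion absorption
  stay flat.  The attribution gradients chain exactly through both
  normalizations.
* **BatchNorm recalibration.**  With few optimizer steps per epoch, BN
  running averages lag the weights and inference-mode outputs can explode
  (a silent post-ReLU channel has near-zero variance, making the
  normalization gain enormous).  Before each validation pass the running
  statistics are reset to the statistics of a fixed training subsample
  (momentum-1 pass, dropout off), and the phantom preset uses a variance
  floor `bn_eps = 1e-3`.  Gradient clipping (global norm 2) guards the
  small-batch updates.

## Evaluation

LOSO cross-validation: one fold per subject, sorted subject order, each
subject tested exactly once; a leakage audit is part of the test suite.
Inside each fold, two training subjects (drawn deterministically from the
fold seed) are held out for early stopping, so validation never sees the
test subject.  Metrics: MAE, RMSE, R² (1 − SS_res/SS_tot about the truth
mean; flagged undefined for constant truth), and threshold accuracies
Acc@±1/2/3 days in percent.  Reports carry per-fold metrics, their
unweighted mean (the convention used for headline tables), pooled-over-all-
predictions metrics (the primary R², since per-fold R² on a handful of
samples is unstable), stage-wise MAE, and per-day prediction summaries.
Healing stages partition age: early 0–3, middle 4–9, late ≥ 10 days
(observations beyond day 20 count as late).  Ages are not rounded before
metric computation.

## Band importance and spectral configurations

Four input configurations reuse the same architecture: an RGB-like triplet
(nearest bands to 460/540/650 nm, Bayer-filter peak sensitivities), a
six-band physiological subset adding 504/569/578 nm (heme-degradation
chromophores), the full band set, and a data-driven Top-20.  Attribution
combines two methods on one tuning-split model (not per LOSO fold), using a
held-out evaluation subset:

* **SmoothGrad:** input gradients over 25 Gaussian-noise draws (noise SD =
  10 % of the input SD); per band, the gradient is averaged over the pixels
  of a sample first — random pixel-level fluctuations cancel in this mean,
  while a band the model systematically uses keeps a coherent sign — and
  the magnitude of that per-sample channel sensitivity is then averaged
  over samples and draws.
* **Occlusion:** each band in turn is replaced by its per-band training mean
  (removing information without leaving the input manifold; zero and
  identity replacements exist as policy flags) and the MAE degradation is
  recorded (signed).

Within each method bands are ranked descending (rank 1 = most important,
ties averaged); the consensus is the mean of the two ranks, and the Top-20
are the bands with the smallest consensus rank, ties at the cut broken
toward the lower band index.

## Synthetic phantom generator

No public dataset exists for this task, so the package ships a generator
that emulates the study design the analysis assumes: a cohort of subjects
(default 8) imaged at ages {0,1,2,3,4,5,6,8,10,13,16,20} days, cubes of 60
bands spanning 400–1000 nm with white/dark reference spectra, and a
ground-truth lesion mask per acquisition.

* **Chromophores** are Gaussian-peak approximations on the stated absorption
  maxima (oxyhemoglobin 415/540/578 nm, deoxyhemoglobin 430/555 nm,
  bilirubin 460 nm; FWHM 20 nm for the Soret peaks, 25 nm for Q-bands and
  bilirubin), each unit-normalized; melanin is a monotone-decreasing
  power-law background.  They are parametric stand-ins, not tabulated
  extinction spectra.
* **Kinetics:** hemoglobin decays exponentially (0.12/day) from its age-0
  maximum; the oxygenated fraction relaxes with a 3-day time constant;
  bilirubin follows a gamma-shaped pulse peaking near day 7, exactly zero at
  age 0; all lesion weights are multiplied by a smooth fade factor
  exp(−(t/22)³) so contrast vanishes toward the resolution horizon.  Per
  subject, the decay rate and bilirubin peak day are jittered ±10 %.
* **Rendering:** lesion reflectance is the subject's skin baseline (melanin
  level and brightness drawn per subject) attenuated by
  exp(−Σ w_c A_c(λ)), modulated by a Gaussian radial falloff whose radius
  grows from 10 px to ~20 px at day 6 and shrinks again, and by a smooth
  multiplicative texture field (Gaussian-filtered noise, correlation length
  4 px) whose amplitude ramps linearly with age up to 0.35 at day 20.  The
  age signal is thus deliberately split between spectral composition and
  spatial texture: spatial averaging destroys the texture channel, which is
  what gives the CNN-vs-Lasso comparison its teeth.  Radiance is dark +
  reflectance × (white − dark) with multiplicative (1 %) and additive
  (0.005) Gaussian sensor noise applied to radiance only.
* **Determinism:** one integer seed drives everything through per-subject
  `SeedSequence` spawn keys, so adding a subject never perturbs existing
  subjects' data.  An optional visibility threshold on the total chromophore
  weight emulates the exclusion of acquisitions without a visible hematoma.

What the phantoms do *not* model: radiative transfer or depth-resolved
structure, spatially varying illumination, camera spectral response, motion,
or real biological variability in healing kinetics beyond the rate jitter.
Passing tests therefore demonstrate that the pipeline recovers the structure
the generator encodes — not clinical performance on real lesions.

## Problem sizes

The numpy implementation runs on one CPU core, so the shipped experiment
configurations are desk-scale, chosen once: phantom cohorts of 8 subjects ×
12 ages × 60 bands, 64×64 px images, 48×48 patches; CNN preset with
spectral channels (4,4,4), spatial channels (8,16), head width 32, batch 4,
lr 3e-3, ≤ 8 epochs, patience 3, gradient clip 2, BN recalibration on 16
training samples; the single attribution model trains longer (≤ 20 epochs),
since band attribution needs a converged model and one model can afford
what a LOSO sweep cannot; Lasso exactly as at full scale.  Patch size matters
scientifically, not just computationally: with small lesion-centered
patches the spatially averaged spectrum is nearly a sufficient statistic
and the averaging baseline is very strong; the 48 px window keeps the
surrounding-skin fraction that gives spatial modeling its advantage.  The
full-width architecture is constructed and shape-verified in the test
suite; the desk-scale preset is the same architecture family at reduced
width.  Attribution uses up to 8–32 evaluation samples.
`scripts/acceptance.py` re-runs the entire grid at this scale from one
seed.

## Numerical choices and degenerate inputs

* Normalization (raw − dark)/(white − dark) is computed in float64 and the
  result stored as float32, unclipped; a zero denominator raises an error
  naming the band and pixel.
* Patch windows clamp to the image instead of padding, so every patch
  contains only real pixels; centroids round half-up; 0-based (row, col)
  indexing with half-open windows throughout.
* The builtin lesion localizer scores pixels by spectral angle to the
  box-border median spectrum, thresholds by Otsu, and keeps the largest
  8-connected component; a contrast floor (0.01 rad, configurable) converts
  "nothing there" into an explicit exclusion, mirroring the removal of
  acquisitions without visible hematomas.  External masks can be injected
  instead, and ground-truth masks are used where available.
* Constant regression targets: the Lasso fit degenerates gracefully to the
  intercept; R² is flagged undefined rather than fabricated.
* Adaptive pooling uses floor/ceil bin edges (bins overlap when the output
  is longer than the input), max-pool gradients follow the first maximum.

## Known limitations

* The phantom's age signal is spectrally low-dimensional (one decaying and
  one unimodal chromophore plus a texture ramp), so a handful of
  well-placed bands — even the RGB-like triplet — captures most of it and
  small input sets generalize well from small cohorts.  Real hematoma
  spectra are richer; conclusions about how *many* bands are needed do not
  transfer from phantoms.

* The phantom is a statistical emulation; none of the reported numbers are
  comparable to results on the clinical dataset the analysis design comes
  from.
* The CNN preset is sized for a single CPU core; at these widths the model
  is far below the capacity of the full-scale architecture.
* The builtin segmenter assumes a single dominant lesion; multiple lesions
  in one frame would be reduced to the largest component.
* SmoothGrad and occlusion agree on the phantoms' informative region, but
  consensus ranking inherits both methods' blind spots (e.g. perfectly
  correlated bands share importance arbitrarily).
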