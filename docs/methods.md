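# Methods

## Circular-kymograph velocity estimation

A treadmilling ring shows an intensity pattern that translates along its
circumference. The estimator treats the kymograph *K*(*s*, *t*) — intensity
at arc sample *s* (of *n* ≈ 2π*r* samples, one per pixel of arc) and frame
*t* — as a superposition of traveling waves cos(2π*f t* − *q s*). For any
spatial harmonic of a rigidly translating pattern, temporal frequency and
wavenumber are tied by the pattern speed, so the phase of the temporal FFT
at the dominant frequency *f*\* falls on a line in *s* whose slope is the
wavenumber *q*, and

v = 2π f\* / |q| · Δs (nm/s),  Δs = pixel size.

This identity holds per harmonic, so the estimate does not depend on which
harmonic dominates. The sign convention: angles are measured from +x toward
+y with the image row axis pointing down, so increasing arc index runs
clockwise on screen; *q* > 0 (pattern advancing toward larger *s*) is
reported as clockwise.

Processing chain and defaults:

- **Mean filter** 3×3 per frame; optional drift correction by integer-pixel
  phase correlation against frame 0 (warn above 25% of the frame, still
  applied).
- **Ring fit**: initial circle = seed segment as diameter; refined by
  Nelder–Mead maximisation of the mean time-averaged intensity on the
  circle, accepted only within ±5 px of the seed circle, otherwise the seed
  circle is returned flagged unrefined. The intensity ridge of a blurred
  annulus sits slightly inside the true radius (curvature + PSF), giving a
  small (~1–3%) downward diameter bias visible in the ring-size experiment.
- **Kymograph**: bilinear sampling on circles *r*−1, *r*, *r*+1 px,
  averaged; rows wrap circularly.
- **Savitzky–Golay** along time, window 7, order 2 — the shortest window
  that suppresses shot noise without attenuating the ~0.02 Hz band at 3-s
  sampling. **CLAHE** with clip limit 0.01 and 8×8 tiles (mild,
  conventional defaults).
- **FFT**: per-row temporal FFT after removing the row mean, zero-padded
  4×. Padding interpolates the spectrum so a peak falling between the
  coarse bins of a 100-frame acquisition is not attenuated (up to ~40%
  scalloping loss otherwise, which would push genuinely rotating rings
  under the fixed acceptance gate). The peak search excludes DC and
  frequencies above half Nyquist (treadmilling bands sit far below it);
  the peak-to-mean ratio uses all non-DC bins.
- **Quality gates**, applied per contiguous block of 50 arc samples:
  spectral peak ≥ 10× the mean magnitude and phase-line R² ≥ 0.95. Blocks
  tile the arc (no sliding); a ring shorter than one block is analysed
  whole. The ring estimate is the peak-ratio-weighted mean of accepted
  blocks, with *v* recomputed from the pooled *f*\* and *q* so the speed
  identity holds exactly. A ring with no accepted block is reported
  static/rejected.

At 100 frames × 3 s the padded frequency grid limits *f*\* to ~1–3%
accuracy, which dominates the speed error of accepted rings (median ~1.5%
at SNR 3 in the recovery experiment).

## Single-molecule residence times

Detection is difference-of-Gaussians bandpass (σ = 1 and 4 px) followed by
local-maximum picking and an iterative brightness-weighted centroid over a
3-px-radius window: the window-border mean is subtracted as local
background, weights are tapered by a Gaussian (σ = 1.8 px) to suppress edge
noise, and the window is recentred up to three times. The taper keeps the
scatter near the background-noise information bound
(σ ≈ noise/amplitude · √(2/π) per axis) with negligible (<0.02 px) bias.

Linking is greedy nearest-neighbour between consecutive frames (closest
pairs first, each spot used once, 10-px radius, no gap closing): at
single-molecule sparsity this coincides with globally optimal matching.
Tracks touching the first or last movie frame are censored and excluded by
default. Residence time is the first-to-last-detection span
(*n* − 1)·Δ*t*; single-frame events are below the method's accuracy and
excluded, so the shortest retained residence is one frame interval.

The survival function (fraction of residences ≥ *t*, evaluated at frame
multiples) is fitted with

S(t) = (1 − B) e^(−k t) + B e^(−kp t),  B ∈ [0.2, 0.25]

with *kp* fixed at the immobilised-fluorophore calibration (0.031 s⁻¹,
timescale ~32 s) by default, or co-fitted on request (with a degeneracy
warning when *kp* ≈ *k*). *A* + *B* = 1 is enforced so *S*(0) = 1. The
model is normalised by its value at the smallest observed duration
(conditional survival). This choice makes the fit exact under the two
discrete effects in the data: for exponential dwells observed on a frame
grid with uniform birth phase, P(*m* ≥ *n*) ∝ e^(−k n Δt), so both frame
discretisation and the short-event truncation change only the prefactor,
not the decay rate. The naive sample mean is biased upward by the cut; the
fitted *k* is not (asserted on simulation). Fitting uses bounded
least squares (lmfit); fewer than 100 events triggers a warning.

## Synthetic data

The generators emulate the statistical structure the estimators assume, not
the polymer mechanics:

- **Ring movies**: *n* arcs of uniform linear density and fixed length on a
  circle, rotated rigidly by ω = v/r per unit time, blurred by a Gaussian
  PSF (σ 1.3 px), scaled so the brightest noiseless pixel equals the photon
  scale, Poisson-sampled, plus Gaussian read noise over a constant
  background. Defaults: 0.042 µm pixels, 3-s frames, 0.5-µm radius, two
  arcs of 390 nm placed evenly (one centred at the bottom of the circle so
  the layout is mirror-symmetric and negating the speed exactly
  column-flips the noiseless movie). Two evenly spaced arcs make the
  kymograph's dominant spatial harmonic *m* = 2, whose temporal frequency
  at 34 nm/s is ~0.022 Hz — the characteristic frequency real rings show —
  and keep the 108 nm/s condition inside the usable frequency band at 3-s
  sampling. SNR is defined as peak amplitude over total noise sd at the
  peak; `photon_scale_for_snr` inverts that definition.
- **Adsorption traces**: saturating-linear (or exponential) ramp plus
  Gaussian noise, for the time-zero synchronisation rule (first crossing of
  200 A.U.; the density-regime boundaries 450/1,000 A.U. are instrument
  -specific conventions exposed as parameters).
- **Single-molecule channel**: homogeneous-Poisson appearances, uniform
  positions, immobile molecules rendered as Gaussians for their whole
  dwell; dwells drawn from a two-population mixture — a fraction *B*
  bleach-limited (Exp(*kp*)), the rest unbinding-limited (Exp(*k*)) —
  matching the fitted model's form; a competing-risks mode (both clocks per
  molecule, minimum wins) is available. Defaults: 1 fps, SNR 5,
  *B* = 0.22, *kp* = 0.031 s⁻¹.

What passing the synthetic-recovery tests does **not** show: robustness to
filament-level intensity fluctuations, ring drift/deformation, mobile or
blinking fluorophores, non-uniform illumination, or camera-specific noise;
the generators model none of these. Quality-gate thresholds (10-fold peak,
R² 0.95) and the A.U. density boundaries are meaningful under acquisition
settings comparable to the defaults.

## Problem sizes

The validation experiments use 20 rings per speed×chirality condition at
SNR 3 (plus 20 static rings), 5,000 disappearance events per kinetic
regime, 3,000-event bleaching controls and 140 simulated rings for the
diameter distribution — matched to the event counts the measurements are
designed for, and small enough that the full suite runs in well under a
minute.

## Known limitations

- Chirality is defined in displayed-image orientation; movies saved with a
  flipped axis convention will report the opposite sense.
- The ring fit assumes a roughly circular, stationary ring; strongly
  deforming or drifting rings need the drift correction and still assume a
  fixed circle over the analysis window.
- The B ∈ [0.2, 0.25] photobleaching-weight constraint encodes the
  labelling stoichiometry of the original assay; other labelling schemes
  need different bounds.
- Greedy linking degrades when concurrent spot density approaches the
  10-px link radius (molecule collisions merge or extend tracks); the
  residual <5% dwell mismatches in the sparse-field test are of this kind.
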