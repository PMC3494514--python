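# Methods

This note documents the models and procedures implemented in `lcquant`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Signal model and pre-processing

A run is an RT-ordered sequence of MS1 spectra.  Processing is targeted
throughout: only the quantifier m/z values on the ion list are ever traced,
which keeps the per-run cost linear in (scans × targets) and sidesteps
untargeted feature detection entirely.

**Smoothing.** Savitzky–Golay filtering (scipy's implementation, mirrored
edge padding) is applied to the extracted-ion chromatogram, not to the
spectra — chromatographic noise, not spectral noise, is what destabilizes
border detection.  SG reproduces polynomials up to its order exactly, so
well-sampled peak apexes and heights are essentially unbiased.  A switch
(`sg_window = 0`) disables it.

**Centroiding.** Profile spectra are reduced to sticks at local maxima whose
summit exceeds `noise_level`; each stick's m/z is the intensity-weighted mean
over the maximum's contiguous above-noise neighbourhood (split at interior
minima when several maxima share a run, the valley point joining neither
side) and its intensity is the summit value.  When a file does not declare
profile/centroid, the mode is inferred from gap uniformity — profile grids
have essentially all consecutive m/z gaps near the median gap; a spectrum
with fewer than 90% of gaps below twice the median is treated as centroid —
and the inference is logged.

**EIC construction.** For each target the per-spectrum contribution is the
sum of centroid intensities within ± `mz_tolerance` (absolute Th, default
0.1 — appropriate for single-quadrupole resolution; tighten for high-res
data).  Spectra without a match contribute explicit zeros, so every EIC
spans the full scan grid; gap splitting (`max_scan_gap`) is available but
off by default.

**Deconvolution.** Peak borders are local minima of the (optionally
smoothed) EIC.  Pure local minima over-segment noise, so a minimum splits
two peaks only if its intensity is at most `min_valley_ratio` times the
smaller adjacent apex (default 0.66).  A candidate segment whose raw maximum
sits on a shared border is the flank of its neighbour, not a peak, and is
discarded — without this rule a single clean Gaussian yields spurious "tail
peaks" at its base.  Heights, apexes (leftmost scan on plateaus) and
trapezoidal areas are always measured on the raw trace; areas are in
intensity·minutes.  Three presets bundle the parameters in order of
detection sensitivity — fast (no smoothing, valley ratio 0.5), default
(SG 7/2, 0.66), thorough (SG 11/3, 0.8) — and every field can be overridden.

## Retention-time alignment

LC drift is modelled as a warp `rt_sample = f(rt_reference)` from
{identity, linear, quadratic}.  Quadratic is the smallest family that
captures non-linear drift while staying monotonicity-checkable in closed
form; a non-monotone quadratic fit falls back to linear, and too few
candidate pairs degrade the model quadratic → linear → identity with a
warning rather than an error.  Candidate pairs are all (reference, sample)
peak pairs matching within `mz_tolerance` and `rt_pre_tolerance` (default
1.0 min); the over-complete set is resolved by RANSAC — minimal subsets are
fitted for `iterations` (default 1000) draws, inliers counted at
`inlier_threshold` (default 0.05 min), and the consensus-maximal model is
refit by least squares on its inliers.  The RANSAC seed is part of the
project configuration, making the entire pipeline deterministic.  The
reference frame is the first standard run, where expected RTs are seeded.

**Suggestion rule.** The suggested peak is the one nearest (in apex RT) to
the warped expected RT within ± `rt_window` (default 0.5 min) — nearest,
not highest, because low-abundance analytes genuinely produce small peaks.
The converse failure (snapping to a baseline blip while a taller peak sits
in the window) is marked by the `not_highest` flag; an empty window yields
`out_of_window`.  The red-flag range is the same `rt_window` used for
suggestion.  Manual integration bounds can override any cell; such cells
are flagged `manual` and integrate the raw trace between the given bounds.

## Calibration and inverse prediction

Six families relate area to concentration (see README for the equations).
All fits minimise squared residuals on the area scale: the linear-in-
parameter families (linear, logarithmic, quadratic, cubic) by linear least
squares, power and exponential by log-linearised initialisation followed by
Levenberg–Marquardt refinement on the area scale — refining on the log
scale would minimise relative rather than absolute error; both R² values
are recorded in the calibration report.  Minimum distinct standard levels
equal the parameter count (2/2/2/2/3/4); fewer than six standards logs a
recommendation warning; replicate levels are pooled; zero-concentration
standards are excluded from logarithmic/power fits with a warning.
Unweighted fitting is the default, with 1/C and 1/C² weighting available
(standard bioanalytical practice for heteroscedastic responses).

**Best-fit suggestion** ranks by R² with ties (within 1e-4) broken toward
fewer parameters, so a perfectly linear response is reported linear rather
than as a degenerate cubic.  The family is fixed per metabolite at
calibration time and recorded in the report.  An adjusted-R² ranking was
evaluated and showed no accuracy benefit on the synthetic benchmark, so the
simpler rule stands.

**Inversion** uses closed forms for the two-parameter families, quadratic
root selection restricted to the calibration range (the nearest real root
is used and flagged when none lies in range; if both roots are in range the
curve is not injective there and the ascending-branch root is taken), and
bracketed Brent root-finding on the monotone branch covering the range for
the cubic.  Concentrations outside [c_min, c_max] carry the `extrapolated`
flag; a 1e-9-relative tolerance keeps floating-point round-off at the range
ends unflagged.  With an internal standard defined, all areas — standards
and samples — are divided by the IS area of their run before fitting or
inversion; a run whose IS peak is missing has every cell marked missing
with a `normalization_error` flag, since no valid area scale exists for it.

## Synthetic data

The generator emulates the aspects of LC-MS data this pipeline is sensitive
to: Gaussian chromatographic peaks (default σ = 0.11 min ≈ 15 s FWHM) on a
uniform scan grid (0.05 min), rendered as profile spectra with a symmetric
three-point m/z support per stick; constant baseline plus white Gaussian
detector noise (clipped at zero); spurious baseline blips Poisson-placed in
RT with log-uniform heights capped at the 25th percentile of true peak
heights; and monotone quadratic RT drift per run, bounded by 0.5 min over a
20-min gradient.  Peak areas follow each metabolite's ground-truth
calibration family, so recovery can be scored at every stage.

Stated SNR values are referenced to the limiting peak of a campaign — the
least-responsive analyte at the lowest standard level — so the nominal SNR
holds for every quantified peak rather than only the typical one.

Scenarios (fixed study conditions, not tuning dials):

- `linear_small` — 3 metabolites, 3 standards (10/50/100 µmol/L), 2
  samples, no drift, no noise.  Exactness checks.
- `six_family` — one metabolite per calibration family, 6 standards,
  noise-free.  Family identification.
- `crowded_baseline` — 8 metabolites with response factors spread 600–4800
  (the weakest analytes sit near the baseline), 4 spurious blips per
  minute, drift, SNR 20, suggestion window 1.0 min.  The adversarial
  fixture for alignment and the `not_highest` red flag.
- `paper_scale` — 29 metabolites, 6 standards (5–100 µmol/L), 12 samples,
  drift + SNR 20, no spurious blips (those are `crowded_baseline`'s stress
  condition).  The desk-scale end-to-end benchmark; sample truths are drawn
  log-uniformly inside the calibration range.

What the generator does **not** emulate: peak tailing (exponentially
modified Gaussians), ion suppression between co-eluting analytes, isotope
envelopes, adduct series, and m/z miscalibration.  Passing tests therefore
demonstrate the mechanism — drift-robust peak assignment and calibration
inversion — not performance on real matrices, where those effects dominate
the error budget.

## Validation procedure and problem sizes

The acceptance script and the system-level tests run, per invocation:
20-point inverse-prediction grids for all six families; noise-free and
2%-multiplicative-noise parameter recovery at n = 6 standards; RANSAC
recovery of a quadratic drift (a₂ = 0.002) from 20 landmarks with 20% gross
outliers; 50 seeded replicates of the `crowded_baseline` campaign for
suggestion accuracy; and 50 seeded replicates of the `paper_scale` campaign
(17 400 quantified cells) for the end-to-end relative-error distribution,
binned at 0–5/5–10/10–15/>15%.

One statistical caveat is handled explicitly: on a six-point design the
polynomial bases are strongly collinear, so individual quadratic/cubic
coefficients cannot be pinned to 10% from a single noisy draw (their
theoretical sampling sd exceeds that bound for any design examined).  Noisy
recovery for those two families is therefore scored on the median estimate
across 11 seeded replicates — a check of unbiased recovery — while the four
two-parameter families are scored from a single fixed draw.

## Known limitations

- MS/MS and MSⁿ data are out of scope; only MS1 spectra are used, and
  spectra lacking an explicit MS level are assumed (and logged) to be MS1.
- No baseline subtraction: peak areas include whatever pedestal survives
  the centroid noise threshold.  With matched standards this cancels
  through the calibration, but strongly drifting baselines would bias
  results.
- One internal standard at most; per-analyte isotopic internal standards
  are not modelled.
- Star alignment only (every run is warped to the first standard); no joint
  multi-run alignment, no m/z recalibration.
- The offline compound-ID table is a small curated snapshot; online lookup
  is deliberately not performed.
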