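# Methods

`renalqmri` is a simulation-and-analysis pipeline for the non-invasive MRI
assessment of kidney grafts harvested after donor cardiac death (DCD/CD
grafts). It models the measurement chain end to end — digital phantom,
forward signal simulation, quantitative mapping, region-of-interest (ROI)
summarization, small-sample statistics, histological congestion
quantification, and a rule-based viability call — so that each stage can be
validated against closed forms and against the published reference values the
presets encode.

## The imaging problem

Warm ischemia after cardiac death causes erythrocytes to plug the capillary
plexus of the inner stripe of the outer medulla ("red cell congestion", RCC).
Deoxyhemoglobin in trapped red cells shortens T2*, so congestion appears as
signal loss on T2*-weighted (BOLD) gradient-echo images. Ischemia also drives
two kinds of edema with opposite diffusion signatures: interstitial edema
raises the apparent diffusion coefficient (ADC), cellular edema lowers it.
The joint pattern — depressed inner-stripe SI ratio plus outer-stripe ADC
decrease plus inner-stripe ADC increase — marks grafts that will not function
after transplantation; grafts harvested at 0 or 1 h tolerate transplantation,
2 h grafts do not.

## Phantom model

A single 1 mm longitudinal slice on a 256x128 grid over a 100x50 mm field of
view (0.390625 mm isotropic pixels, printed nominally as 0.39 mm). The kidney
is an ellipse (semi-axes 0.46/0.42 of the grid) partitioned into four nested
elliptical bands — cortex (CTX), outer stripe (OS), inner stripe (IS), inner
medulla (IM) — with area ratios 40:15:15:30 of kidney area. No source states
compartment areas; these ratios were fixed once for plausible band widths at
this resolution and all tests are geometry-independent (ROIs come from the
label map).

Each phantom draws one T2* (ms) and one ADC (10^-3 mm^2/s, numerically equal
to 10^-9 m^2/s) value per compartment from the condition preset's
Normal(mean, SD), truncated to positive; zero-SD presets reproduce the means
exactly, which is how the noiseless round-trip checks are built. The preset
library carries the measured compartment averages (n = 3 kidneys per arm) for
unperfused grafts, grafts perfused with University of Wisconsin (UW)
solution, and the CD0h before/after 3 h UW-incubation pair.

RCC is represented as a boolean lesion mask: per compartment, the requested
pixel fraction is selected by thresholding a Gaussian-smoothed random field
at the exact count quantile, giving contiguous blobs and a realized fraction
accurate to the nearest pixel. A configurable factor can additionally
multiply T2* inside the mask (mechanistic deoxyhemoglobin signal loss;
0.35 is the dataclass default). Table-derived presets set this factor to 1.0:
their compartment T2* values are measured averages that already include the
congestion effect, and applying the factor again would double-count it.
Default severities (IS 0.35/0.40 for CD1h/CD2h vs 0.03 for CD0h, mild
elsewhere; partial IS washout for CD1h after UW perfusion) are package
choices — the corresponding published quantifications exist only as figure
axes — selected once to reproduce the qualitative pattern, not any magnitude.

## Signal model

Gradient-echo: S(TE) = S0_eff exp(−TE/T2*). Proton density and the
TR/flip-angle steady-state weighting are folded into the single multiplicative
field S0_eff (uniform 1000 au in tissue) because each sequence is analyzed at
one TR/flip setting and all contrasts of interest are T2*/diffusion driven.
Diffusion-weighted spin echo: S(b) = S0_eff exp(−b·ADC) with b in s/mm².
No k-space effects, partial volume, susceptibility or eddy currents are
modeled.

Noise is optional and seeded: Gaussian, or Rician magnitude reconstruction
sqrt((S+e1)² + e2²) with e ~ N(0, σ) — the correct model for magnitude MR,
with a Rayleigh background of mean σ√(π/2). `n_averages` independent
acquisitions are averaged (Gaussian SD scales as σ/√n, matching the
two-average protocol). Acceptance-grade runs use σ = 0.

The reference protocol acquires BOLD at a single TE (10 ms); how the
published per-compartment T2* values were derived from it is not stated.
This package therefore simulates multi-echo data (default TE = 5, 10, 20,
40, 80 ms) and fits T2* explicitly rather than guessing the original
procedure; the single-TE frame doubles as the SI map.

## Parameter mapping

- **T2***: per-pixel log-linear least squares on ln S = ln S0 − TE/T2* over
  ≥ 2 distinct echoes. Exact on noiseless data and adequate at the noise
  levels used here; pixels with any non-positive signal or a non-negative
  slope are masked invalid (never clipped) and counted by the ROI stage.
- **ADC**: two-point formula ADC = ln(S_low/S_high)/(b_high − b_low),
  reported in 10^-3 mm²/s, defaults b = 0 and 134 s/mm². The published
  equation text renders as "ln[S_1 + S_h]/(b_h − b_1)", which is
  dimensionally inconsistent with the stated signal model; the standard
  two-point ratio form is implemented, and it reproduces the published value
  ranges. Negative estimates (S_high > S_low) are masked invalid but kept in
  a diagnostics channel.
- **SI ratio**: per kidney and compartment, single-TE signal intensity
  divided by the mean SI of the CD0h reference group for that compartment
  (computed from the SI values as stated, not from fitted T2*).

Noiseless round trips (simulate → map) recover the ground-truth maps to
≤ 1e−9 relative error; this is asserted per pixel.

## ROI protocol and group statistics

ROIs are pixel-index sets fixed on the reference grid and applied verbatim to
every co-registered map — the in-silico equivalent of a "restore selection"
workflow. Grid mismatch is an error by design; no resampling or registration
is attempted. The replicate unit is the kidney (n = 3 per arm in the
reference tables), never the pixel: group summaries are mean and sample SD
(n−1 denominator) over per-kidney compartment means.

Tests between two arms use the pooled-variance two-sided t from (mean, SD, n)
summaries; within-kidney comparisons use the paired t on differences; three
or more arms use one-way ANOVA with Tukey-Kramer adjusted pairwise p-values
from the studentized-range distribution (scipy's numerical CDF, tolerance
well below 1e−6). Two-sidedness is adopted because the four recomputable
published p-values match the two-sided pooled t at printed precision.
Degenerate zero-variance inputs are flagged: equal means give p = 1, unequal
means p = 0.

One of the four recomputable cells (IS ADC, CD0h vs CD2h) recomputes to
0.0211 from the printed 3-decimal summaries versus 0.0213 as printed; a
rounding-envelope scan over the printed inputs spans [0.0201, 0.0221], so the
printed value reflects unrounded raw data. The test suite asserts printed
precision for all four cells and documents this one as the known exception.

## Histology quantification

Synthetic eosin sections render tissue pale pink (225,170,190), trapped red
cells saturated red (240,50,60) and lumen near-white, with Gaussian pixel
noise (SD 6). Congestion truth masks reuse the blob generator, so requested
area fractions are exact to the nearest pixel. Segmentation scores each pixel
by redness r = R − (G+B)/2, thresholds at 95 (calibrated to the synthetic
stain only), and removes connected components under 5 pixels to suppress
speckle. Dice against the generator truth exceeds 0.95 by construction;
no claim is made about real whole-slide images, scanner color variation, or
stain deconvolution (a hook exists but raw-RGB redness is the default since
the synthetic stain is separable by construction).

## Viability rule

Three boolean flags against the CD0h reference: IS SI-ratio depressed,
OS ADC decreased, IS ADC increased. Each fires when the metric deviates from
the reference mean by more than 2 reference SDs in the indicated direction
(strict inequality; boundary values do not fire). The default call is the
conjunction of all three — chosen so that CD1h grafts, which show congestion
but not the two-edema ADC pattern, classify as functioning, matching their
post-transplant outcome. The margin and the rule expression are configurable;
no numeric thresholds exist in the source material, so the 2-SD margin is a
package convention, surfaced in every output. Thresholds are anchored to the
published CD0h reference table (means and SDs), not to the simulated CD0h
cohort of a given run: that mirrors how reference values would be applied to
a new kidney and keeps zero-variance validation runs non-degenerate. The
SI-ratio reference SD is the CD0h group's coefficient of variation of SI,
obtained from the T2* spread by first-order propagation
(CV_SI = TE/T2*² · SD_T2*).

On a zero-variance cohort carrying the table values verbatim (3 kidneys per
arm), the classifier is 9/9 against condition-derived outcomes. On cohorts
sampled with the published SDs the unperfused arms overlap — as the source
data themselves do — and accuracy is seed-dependent; UW perfusion widens the
separation, which the sampled-cohort tests assert as orderings and 2-SD
flags, never as magnitudes.

## Problem sizes and numerical choices

Default grids are 256x128 (full resolution) for acceptance-grade runs and
64x32 for high-repetition tests (e.g., 600 sampled kidneys for the
cohort-SD check). Monte-Carlo oracles use 10^6 draws for the
studentized-range comparison (tolerance 0.01) and 10^4 null simulations for
type-I-error calibration (0.05 ± 0.01). All randomness flows from
numpy SeedSequence children of a single user seed; identical configuration
and seed reproduce every output byte-for-byte. Ties in the blob-count
quantile are trimmed deterministically in ravel order.

## Known limitations

- The phantom is 2D, piecewise-constant per compartment, with no vasculature,
  nephron microstructure, partial-volume mixing or B0 inhomogeneity; passing
  round-trip tests demonstrates correctness of the estimators, not robustness
  to real acquisition physics.
- The paired t-test exists for protocol completeness but the published
  before/after UW-incubation p-values cannot be recomputed (per-pair
  differences were never printed), so it is validated against first-principles
  oracles only.
- RCC severities and the stain model are synthetic conventions; histology
  segmentation defaults are calibrated to the generator, not to scanners.
- The viability rule reproduces a pattern on synthetic data; no clinical
  validity is claimed.
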