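# Methods

This note records the models, parameter choices and numerical decisions
behind the three analysis arms and the synthetic generators, and what the
test surface does and does not demonstrate about real data.

## Feulgen image cytometry

A digitized Feulgen-stained nucleus is a per-pixel absorbance map with a
physical pixel size (default 0.5 μm, the scanning-spot side of the
microspectrophotometer class this emulates; pixel area 0.25 μm²). Two
absorbance thresholds define the measurement:

* **Removal floor, 0.020** (strict `>`): measuring points at or below it
  are background and are removed from the nuclear image. The nuclear mask
  is defined by this floor alone — no connectivity analysis or hole
  filling — so interior pixels that fall below the floor are excluded from
  S_T. This is the minimal reading of automatic point removal; it is
  flagged here because an instrument that fills vacuole-like holes would
  report slightly larger S_T.
* **Condensed cutoff, 0.100** (inclusive `>=`): nuclear pixels at or above
  it count as condensed chromatin. The inclusive comparison makes the
  cutoff value itself attainable as condensed.

From pixel counts and integrated absorbances, `S_C% = 100·S_C/S_T` and
`AAR = (A_C/S_C)/(A_T/S_T)`. When no pixel reaches the cutoff, AAR is
reported as a missing value (NaN), never 0 or infinity: the ratio is
undefined and downstream statistics drop it explicitly with a logged
count. A provable invariant, asserted property-style in the tests, is
AAR ≥ 1 whenever it is defined.

One numerical detail: S_C% is computed as `100·(S_C/S_T)` (ratio first).
The pixel areas cancel exactly in floating point whenever the pixel area
is exactly representable, so the measured S_C% is bitwise equal to 100×
the ground-truth pixel fraction on noiseless simulations.

## FT-IR processing chain

Spectra live on a descending wavenumber grid (3600 → 800 cm⁻¹ at 4 cm⁻¹,
701 points, the acquisition convention emulated throughout). The chain is
ordered and the order is enforced through a state flag:

    raw → baseline_correct → average_spectra → normalize_max
        → extract_window → detect_peaks → fit_gaussian_peaks

* **Baseline + level-plus-zero correction.** A piecewise-linear baseline
  through the spectrum's own values at four anchor wavenumbers is
  subtracted, then the global minimum is shifted to zero. This is a
  minimal, offset-invariant interpretation of a four-fitting-point
  baseline-plus-offset correction; the proprietary software feature it
  stands in for is undocumented, so the operation is defined by its
  algebra (offset invariance; a spectrum that is a line through its
  anchors maps to zero). Default anchors 3600, 2700, 1800, 800 cm⁻¹ —
  edges of commonly flat regions in DNA spectra — are configurable.
* **Averaging** is the pointwise mean of baseline-corrected replicates on
  one grid (mismatched grids are an error naming the offenders).
* **Normalization** divides by the highest absorption peak; the maximum is
  exactly 1 afterwards and the operation is idempotent. Windowed
  sub-spectra keep the normalized flag without re-asserting the unit
  maximum, since a window need not contain the global peak.
* **Deconvolution window** defaults to 2992–2850 cm⁻¹ (closed interval, 36
  grid points), the C–H/–CH₃ stretching region whose intensity tracks 5mC
  abundance.

### Peak detection

Candidates come from negative minima of a Savitzky–Golay-smoothed second
derivative (window 11 points, polynomial order 3). Each candidate is
snapped to the nearest local maximum of the smoothed curve within two
samples — curvature minima land on the flanks of a noisy summit, and
without snapping twin flank candidates shadow each other — and duplicates
merge. A candidate is kept when its topographic prominence (height above
the higher of the two bases toward nearest higher ground, scipy's
definition) reaches a threshold expressed as a fraction of the window's
absorbance range: low 0.05, medium 0.02, high 0.005. These constants are
implementation choices; "low" deliberately resolves only well-separated
components, mirroring low-sensitivity deconvolution settings that return
few peaks. Shoulder candidates sitting on a monotonic flank have near-zero
prominence and are only recovered by the subsequent least-squares
refinement, not by detection — a known limitation. FWHM guesses use the
Gaussian curvature relation `fwhm = sqrt(8 ln2 · h / |y''|)`.

### Gaussian fitting

Bands are Gaussians parameterized by FWHM; areas use the closed form
`h·FWHM·√(π/(4 ln2))` rather than numerical integration, for exactness and
testability. The fit is bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e-14, evaluation budget
20 000): centers within the window extended by one initial FWHM, heights
in [0, 10× window maximum] (the finite cap prevents a component centered
outside the window from ballooning to model a small pedestal), FWHM
between twice the grid step and the window width. Components whose fitted
height collapses below 1e-6 of the window maximum are pruned.
Non-convergence raises an error carrying best-so-far diagnostics.

On windows that are exact sums of up to three Gaussians whose neighbors
are separated by at least 1.2× the sum of their FWHMs — the resolvability
margin of the detector, established on 2000 simulated draws — parameters
and total areas are recovered to near machine precision; the acceptance
benchmark draws from exactly this family. More overlapped mixtures are not
identifiable from detection-seeded fits and are outside the benchmark.

### Ratios, quality checks, assignments

The –CH₃-bend / cytosine ratio uses point absorbances at the grid samples
nearest 1375 and 1492 cm⁻¹ (ties resolve to the higher wavenumber), not
fitted peak heights; numerator and denominator are parameters because both
orientation conventions appear in practice. Quality checks report a local
absorbance maximum inside 1232–1225 cm⁻¹ (B-form marker), a sign change of
the smoothed second derivative within 1715–1700 cm⁻¹ (base-pairing
shoulder of non-denatured DNA), and the peak absorbances found in the
1240–1220 (ν_as PO₂⁻) and 1100–1070 cm⁻¹ (ν_s PO₂⁻) search windows
together with the boolean `ps_below_pas`. The report deliberately exposes
the two raw absorbances rather than encoding any single ratio convention
for "pure DNA", since the orderings quoted for that criterion conflict
between sources. Band assignment is a fixed lookup over the standard DNA
windows; anything outside them is "unassigned".

## Immunofluorescence quantification

8-bit grayscale fields are segmented by Otsu threshold (fixed-value
override available) into connected components with a minimum size of 50
pixels, ordered by centroid. Touching nuclei merge — a documented
limitation of threshold segmentation. Per-nucleus intensity is the
arithmetic mean minus the median of all non-nucleus pixels; the
subtraction is switchable off for parity with raw ImageJ-style means.
Because intensity comparisons are only meaningful under identical
acquisition settings, batch measurement refuses images with mixed exposure
tags. Dose-direction tests follow the convention that 5mC signal
*decreases* with demethylating treatment.

## Synthetic generators

The generators emulate the statistical structure the analysis assumes and
carry their ground truth, so downstream stages are tested as recovery
problems against the *realized* simulation (not the requested parameters),
removing discretization flakiness.

* **Nuclei**: a circular nucleus (radius in μm) on a zero background;
  condensed chromatin as rejection-sampled disks at `condensed_level`
  (default 0.20) over a `diffuse_level` interior (default 0.06), the last
  disk trimmed pixelwise so the realized blob count matches the requested
  fraction to within one pixel. Disks are non-overlapping while the
  packing allows it; past the packing limit (high fractions) they may
  merge so the target is still met. Noise is additive Gaussian truncated
  at zero, since absorbance is non-negative. A `recoverable` flag enforces
  `condensed_level > 0.100 ≥ diffuse_level > 0.020` so the standard
  thresholds can recover the construction.
* **IR spectra**: sums of Gaussian bands at the standard DNA assignment
  centers (NH/NH₂ 3410, –CH₃ stretch 2935, shoulder 1707, thymine/adenine
  1661, cytosine 1492, –CH₃ bend 1375, ν_as PO₂⁻ 1225, ν_s PO₂⁻ 1080
  cm⁻¹), plus a polynomial baseline (ascending-power coefficients) and
  Gaussian noise. Bands flagged `methylation_scaled` (2935 and 1375) have
  their height multiplied by a methylation level in [0, 1]. Heights and
  FWHMs are generator defaults chosen so the spectrum has the qualitative
  shape of extracted-DNA spectra — global maximum in the NH/NH₂ region,
  ν_s below ν_as, a resolvable 1707 shoulder (FWHM 14 cm⁻¹ keeps its
  curvature inflections inside the 1715–1700 detection window). No
  absolute absorbance magnitudes were available to calibrate against, so
  these defaults are illustrative, not measured.
* **IF fields**: disk nuclei whose interior intensity is
  `background + 40 + 160·methylation_level` (an affine increasing map
  chosen to span the 8-bit range comfortably at background 20), Gaussian
  noise, clipped to [0, 255].

Demo methylation levels {1.0, 0.6, 0.3} labeled control / 1 mM / 20 mM are
illustrative dose-direction settings, not measured values. All generators
are deterministic under a fixed seed.

**What passing tests show — and do not.** Recovery and direction-of-effect
results demonstrate that the measurement chain is algebraically correct
and recovers known constructions; they do not validate the biology or the
instrument physics. The generators omit optics (point-spread,
photobleaching), stain stoichiometry, scattering and instrument-specific
noise, so quantitative agreement with any real dataset is out of scope.
Published group-level numbers for this experimental system (deconvolution
peak counts and areas, absorbance ratios) depend on raw spectra and
micrographs that were never deposited; they are treated as
direction-of-effect references only, never as value targets.

## Statistics

Two-sided Mann-Whitney U throughout, alpha 0.05 (a one-sided alternative
is a flag). The exact null distribution of U is used when the pooled
sample is tie-free with n₁+n₂ ≤ 20 — verified in the tests against
exhaustive permutation enumeration up to 6+6 — and the mid-rank normal
approximation with tie correction otherwise; the path taken is recorded on
every comparison. At the study's group sizes (n = 50 and 30) the
approximation path applies. No multiple-testing correction by default,
matching per-comparison reporting conventions; a Bonferroni flag exists.
Undefined AARs are excluded pairwise with logged counts, not imputed.

## Problem sizes

Defaults were chosen so the whole suite exercises realistic structure at
desk scale: 100-nucleus recovery sweeps (radius 8 μm ≈ 800 pixels per
nucleus), 50-draw deconvolution benchmarks, 100-run dose-direction
ensembles with 6 replicates per group at 1 % noise, 1000-run null
calibration at n = 50 per group, and a three-group demo pipeline with 20
nuclei, 6 spectra and 3 fields per group. The full test suite runs in
well under a minute.
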