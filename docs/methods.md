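# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that affect results.

## Nuclear-translocation scoring

**Model.** A cell has relocated its target protein to the nucleus when the
mean target-channel fluorescence inside the nucleus substantially exceeds the
cytosolic level next to it.  The score is the ratio of the mean intensity over
the nucleus eroded by 1 px to the mean over a perinuclear ring, and a cell is
called positive when the ratio strictly exceeds 4.  The erosion and the 1-px
gap before the ring guard against segmentation-boundary mixing of nuclear and
cytosolic signal; the ring (3 px wide by default) stands in for the cytosol
because adherent cells rarely have a segmentable cytosolic compartment.

**Pipeline choices.**

* Nuclei: Gaussian smoothing (σ = 1.5 px) then a global Otsu threshold.  Both
  are parameterless and reproducible; local/adaptive thresholds were avoided
  because the synthetic benchmark has no illumination gradients and real use
  should make flat-fielding an explicit upstream step, not a hidden one.
* Touching nuclei are split by a distance-transform watershed seeded at local
  maxima at least `split_min_distance` (7 px) apart.  Adjacent plateau maxima
  of even-diameter disks are merged into one marker per connected component,
  so ideal disks are not oversplit.
* Filters: 80 ≤ area ≤ 2000 px² and circularity 4πA/P² ≥ 0.7, with the
  perimeter as estimated by `skimage.measure.regionprops`.  On a digital grid
  circularity of a disk can slightly exceed 1 (observed up to ≈1.10 for r = 6
  px); no upper cutoff is applied.  These cutoffs suit nuclei of 6–10 px
  radius (a 20× objective at typical camera sampling) and are exposed in
  `SegmentationParams` and echoed into every output via a parameter hash.
* Border-touching nuclei are removed by default — their ring would be
  truncated and bias the cytosolic estimate.
* The cell mask thresholds the *log-compressed* target channel.  The channel
  is typically trimodal (background ≪ cytosol ≪ positive nuclei) and a
  linear-scale Otsu can land between cytosol and nuclei, emptying every ring;
  log compression puts the split between background and cell.
* "Pixel distance" is the city-block metric: all erosions/dilations iterate a
  radius-1 diamond structuring element, so "3 px wide ring" means exactly
  three dilation steps.  A Euclidean-disk alternative would differ at corners;
  the iterative convention is the one the tests' independent pixel-loop oracle
  reproduces.
* The ring is clipped to the cell mask and to the complement of *every*
  nucleus dilated by the gap, so neighbouring nuclei never contaminate a
  cytosolic estimate.  Cells whose eroded core or clipped ring is empty, or
  whose ring mean is zero, are dropped and counted in the log — never imputed.

**Invariants.** On a spatially constant target channel every ratio is exactly
1.0; scaling the target channel by any c > 0 changes no ratio and no call;
eroded cores and rings are disjoint pixel sets, and rings never intersect any
nucleus.

## Clamp and tracer quantities

* **Steady state.**  The search scans candidate windows from the end of the
  trace backwards and returns the latest window of at least `window_min`
  (default 15 min) whose GIR coefficient of variation is ≤ `gir_cv_max`
  (default 0.05) and whose mean glucose is within `glucose_tol` (0.5 mM) of
  the target; a qualifying window is extended backwards while the criteria
  continue to hold, so a fully constant trace reports the full-trace window.
  When the window is exactly constant its value is reported directly rather
  than a summed mean, so noiseless plateaus are recovered without float
  round-off.  With noisy traces the backward extension can reach ~1–2% into
  the approach phase at the default CV tolerance; a tighter tolerance (0.02)
  keeps the window on the plateau for high-SNR traces.
* **Turnover and EGP.**  Ra = tracer infusion rate / plasma specific activity
  at isotopic steady state; EGP = Ra − GIR, which reduces to Ra at basal.
  Negative EGP is returned with a warning, not clipped — a negative value
  indicates a data problem the analyst must see.
* **Rg.**  Tissue phospho-2-DG counts divided by the trapezoid integral of
  plasma specific activity over the sampled times.  No curve is fitted: the
  trapezoid on the observed grid is the minimal assumption, and the generator
  quantifies the bias it introduces (≈3% low at the default kinetics and the
  0/2/15/25/35-min grid, because the trapezoid overestimates the integral of
  a convex decay).  No lumped constant is applied by default (an optional
  divisor is provided), so Rg is on the 2-DG scale unless the user supplies
  their own discrimination factor.
* **Glycolysis metrics.**  ECAR glycolysis = max post-glucose − last basal;
  capacity = max post-oligomycin − last basal; reserve = capacity −
  glycolysis.  Scintillation glycolytic flux clips the background-subtracted
  signal at zero: background exceeding sample is counting noise, unlike a
  negative EGP which is physiologically meaningful as a warning sign.
* **AOC.**  Trapezoidal integral of (value − baseline) with the subject's own
  t = 0 value as default baseline; the sign is retained so glucose-tolerance
  excursions are positive and insulin-tolerance dips negative.  The statistic
  is linear in the values and invariant to adding a constant to curve and
  baseline together.

## Mass arithmetic and quantification

Monoisotopic atomic masses are pinned constants (C 12 exactly, H 1.0078250319,
N 14.0030740052, O 15.9949146221, S 31.97207069) so every result is
bit-stable.  The default ionization convention matches how calculated m/z
values are printed in natural-product characterization sections: the formula
as printed is the *ion* composition; negative-mode m/z is its plain formula
mass (no electron-mass correction), positive-mode m/z subtracts one electron
mass (0.000549 Da).  The asymmetry is deliberate — it is the convention the
published anchor values follow — and a physically exact mode (electron
corrected in both polarities) is available behind the `exact` flag.

Rounding: m/z is displayed at 4 decimals, half-up; Δppm at 1 decimal, half
away from zero.  Δppm is computed from 4-decimal m/z values, matching the
evident practice of rounding before the ppm arithmetic.  Note that published
Δppm values are not always self-consistent with their own printed
observed/calculated pairs; only self-consistent pairs are asserted in tests.

Calibration is ordinary least squares of peak area on concentration
(`scipy.stats.linregress`); quantification inverts the line and converts to
% w/w with explicit µg/mL ↔ mg/mL care.  Back-calculated concentrations
outside the calibrated range are flagged, not rejected.

## Dose translation

Body-surface-area scaling with the standard FDA Km factors (human 37, mouse
3): animal dose = human dose × Km_human/Km_animal, rounded half-up at a
configurable granularity (default 10 mg/kg for extract-level doses, none for
constituents).  Diet admixture is dose × body weight / daily intake (defaults
30 g mouse, 3 g food/day).  Fraction doses are percentages of the extract
dose; constituent doses are percentages of their parent fraction's dose —
proportions are treated as given inputs, since reconstructing them from raw
fractionation yields requires data not generally available.

## QC statistics

Grubbs is single-pass and two-sided: G = max|xᵢ − x̄|/s against
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) t-quantile on n−2
df.  Iterative removal exists behind a flag and warns about inflated type-I
error.  ΔΔCt uses one housekeeping reference per call (a multi-reference
geometric mean can be composed by the caller).  ANOVA-family inference is
deliberately out of scope — standard statistical packages do it better.

## Synthetic generators

The generators provide exact ground truth, not realism:

* **Images** are ideal filled disks (radius 6–10 px) with a uniform cytosolic
  annulus, placed by rejection sampling so that no nucleus overlaps another
  and no annulus touches a foreign nucleus, over a flat background with white
  Gaussian noise (σ = 30 on levels 100/500/2500).  Exactly
  `round(fraction × n_cells)` cells are translocated, with the assignment
  shuffled by the seed.  There is no PSF, no chromatic offset, no illumination
  gradient, no nuclear texture, and no cell crowding beyond the packing rule —
  so recovery results certify the measurement arithmetic and the segmentation
  logic, not robustness to real microscopy artifacts.  An infeasible packing
  raises rather than silently truncating.
* **Clamp traces** follow an exponential approach of GIR to the plateau
  (default 36.3 mg/kg/min, a typical insulin-resistant steady-state GIR) at a
  6 mM target with white noise; `approach_rate=inf` gives an exactly flat
  plateau for closed-form checks.
* **Tracer curves** are exactly biexponential (defaults A₁ = 60 000 DPM/mL,
  k₁ = 0.07/min, A₂ = 30 000 DPM/mL, k₂ = 0.02/min — distribution and
  clearance half-lives of ≈10 and ≈35 min, realistic for a 2-DG bolus in the
  mouse).  Tissue counts are `true_rg` × the fine-grid (Δt = 0.01 min)
  integral of specific activity, with small multiplicative noise (0.5%), so an
  estimator integrating only the 5 sampled points is tested against the truth
  including its own discretization bias.

All generators are bit-reproducible under a fixed seed, and with zero noise
each output equals its deterministic model exactly.

## Problem sizes and tolerances in the tests

The benchmark suite scores 20 seeded 1024×1024 fields of 200 cells each
(mean |pct_positive − truth| ≤ 5 percentage points), 50 seeded bolus curves
(median relative Rg error ≤ 5%), and Grubbs critical values for n = 3…30 at
α ∈ {0.01, 0.05} against an independent incomplete-beta quantile oracle
(agreement to 1e−6).  Exact identities (uniform-field ratios, EGP
bookkeeping, AOC closed forms, noiseless plateaus, calibration round-trips)
are asserted without tolerance or at machine precision.

## Known limitations

* Segmentation thresholds, size/circularity cutoffs and the smoothing scale
  are declared defaults, not universal constants; dense or textured real
  images will need tuning via `SegmentationParams`.
* Rg carries the trapezoid discretization bias of its sampling grid and no
  lumped-constant correction by default.
* Steady-state detection assumes the trace ends in (or after) the plateau;
  it does not model glucose-space non-steady-state (no Steele equations).
* The formula grammar excludes isotope labels, charges and parentheses.
* Iterative Grubbs removal, if enabled, inflates the nominal α.
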