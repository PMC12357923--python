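# metaboquant

Quantitative procedures for metabolic phenotyping studies of glucoregulatory
compounds — the kind of work where a plant extract or purified phytochemical is
tested for effects on insulin sensitivity in diet-induced obese mice and its
constituents are characterized by high-resolution mass spectrometry.  The
package bundles, as one tested library with a CLI, the per-study arithmetic
that is usually scattered across ad-hoc scripts and spreadsheets:

* **Nuclear-translocation scoring** (`metaboquant.nuctrans`) — per-cell
  quantification of signalling-protein relocation (e.g. ERK1/2) from
  two-channel fluorescence images.  Nuclei are segmented from the DNA-stain
  channel (Gaussian smoothing, global Otsu threshold, optional
  distance-transform watershed) and filtered by area and circularity
  (4πA/P²).  For each nucleus the mean target-channel intensity is measured
  over the nucleus eroded by 1 px and over a 3-px-wide perinuclear ring
  starting 1 px outside the nuclear border, restricted to the cell area and
  excluding all nuclei.  A cell is *nuclear-positive* when

  ratio = I̅(nucleus ⊖ 1px) / I̅(ring) > 4.

* **Clamp and tracer arithmetic** (`metaboquant.tracer`) — steady-state
  detection on hyperinsulinemic-euglycemic clamp traces (GIR constant to a CV
  tolerance for ≥ 15–20 min at the 6 mM glycemic target); glucose turnover
  Ra = tracer infusion rate / plasma specific activity; endogenous glucose
  production EGP = Ra − GIR; tissue 2-deoxyglucose uptake
  Rg = C*ₜᵢₛₛᵤₑ / ∫₀ᵀ SA(t) dt with SA(t) the plasma tracer specific activity,
  trapezoid-integrated over the bolus sampling times (0, 2, 15, 25, 35 min);
  scintillation-based glycolytic flux; ECAR glycolysis/capacity/reserve; and
  the signed, baseline-referenced area of the curve (AOC) for tolerance tests.

* **Compound-identity arithmetic** (`metaboquant.chemident`) — Hill-formula
  parsing, monoisotopic and adduct m/z under the ionization conventions used
  in natural-product reports (negative mode: plain deprotonated-formula mass;
  positive mode: protonated-formula mass − mₑ), Δppm mass errors, and
  external-standard quantification from an OLS calibration line.

* **Dose translation** (`metaboquant.dosing`) — FDA body-surface-area
  human-equivalent dosing (animal dose = human dose × Km_human/Km_animal,
  37/3 for human→mouse), diet admixture concentrations, and proportional
  apportionment of fraction and constituent doses.

* **QC statistics** (`metaboquant.statsqc`) — two-sided single-pass Grubbs
  outlier test, ΔΔCt relative expression (fold = 2^−ΔΔCt), percent change and
  mean ± SEM/SD summaries.

* **Synthetic ground truth** (`metaboquant.synthetic`) — generators for plate
  images with a known translocated fraction, clamp traces with a plateau at
  6 mM, and biexponential 2-DG bolus curves with tissue counts consistent with
  a chosen uptake rate, so every estimator above can be benchmarked for
  recovery without any external data.

## Worked example

Score a synthetic field of 200 cells of which 60% carry nuclear-enriched
target signal (5:1 nuclear:cytosolic intensity; resident cells 1:1):

```python
from metaboquant import synthetic as syn, nuctrans as nt

nuclei, target, truth = syn.make_image(
    syn.ImageSpec(n_cells=200, translocated_fraction=0.6, seed=42))
records, summary = nt.score_image(nuclei, target)
print(summary)
# ImageSummary(n_nuclei_total=200, n_nuclei_kept=200, n_positive=120,
#              pct_positive=60.0, params_hash='9e06b3f1c5cc')
```

All 200 nuclei survive the size/circularity filters and 120 exceed the
ratio-4 cutoff: the scored 60.0% matches the generator truth.  The same
round-trip works for tracer kinetics — a bolus decaying with half-lives of
≈10 and ≈35 min, sampled at the five bolus time points, recovers a simulated
uptake rate of 0.5 µmol/g/min as 0.484 (−3.3%, the bias of trapezoid
integration on that grid).

Desk arithmetic from the command line:

```sh
$ metaboquant mz --formula C19H17O11 --mode neg   # mangiferin [M-H]-
421.0771
$ metaboquant ppm --obs 421.0776 --calc 421.0771
1.2
$ metaboquant dose hed --human-dose 10.5          # human -> mouse, Km 37/3
130
```

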