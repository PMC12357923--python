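"""Glucose-flux arithmetic for clamp and radiotracer experiments.

Implements the quantities of a hyperinsulinemic-euglycemic clamp with tracer
dilution, plus in-vitro glycolysis readouts:

* steady-state detection on a glucose-infusion-rate (GIR) trace,
* glucose turnover Ra = tracer infusion rate / plasma specific activity
  (isotopic steady state; under clamp Rd = Ra),
* endogenous glucose production EGP = Ra - GIR,
* tissue-specific glucose uptake Rg from a 2-deoxyglucose bolus: trapped
  phospho-2-DG counts divided by the time-integral of plasma tracer specific
  activity (trapezoid over the sampled times),
* scintillation-based glycolytic flux and Seahorse-style ECAR glycolysis
  metrics,
* signed, baseline-referenced area of the curve (AOC) for tolerance tests.

All integrals are trapezoidal on the observed grid; no curve fitting or
compartmental modelling is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClampTrace",
    "TracerSample",
    "SteadyState",
    "FluxResult",
    "tissue_uptake",
    "detect_steady_state",
    "glucose_turnover",
    "egp",
    "rg_from_bolus",
    "glycolytic_flux",
    "ecar_metrics",
    "aoc",
]


@dataclass
class ClampTrace:
    """Timestamped clamp series: blood glucose (mM) and GIR (mg/kg/min)."""

    time: np.ndarray  # min, strictly increasing
    glucose: np.ndarray  # mM
    gir: np.ndarray  # mg/kg/min
    insulin_infusion: float = 12.0  # mU/kg/min
    target_glucose: float = 6.0  # mM

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.gir = np.asarray(self.gir, dtype=float)
        if self.time.size == 0:
            raise ValueError("empty clamp trace")
        if not (len(self.time) == len(self.glucose) == len(self.gir)):
            raise ValueError("time/glucose/gir lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.gir < 0):
            raise ValueError("GIR must be non-negative")


@dataclass(frozen=True)
class TracerSample:
    """One scintillation measurement (plasma or tissue)."""

    time: float  # min
    plasma_dpm: float = float("nan")  # DPM per mL plasma
    plasma_glucose: float = float("nan")  # mM
    tissue_dpm: float = float("nan")  # DPM
    tissue_weight: float = float("nan")  # mg
    tracer_infusion_rate: float = float("nan")  # DPM/min (continuous infusion)


@dataclass(frozen=True)
class SteadyState:
    found: bool
    t_start: float = float("nan")
    t_end: float = float("nan")
    gir_ss: float = float("nan")


@dataclass(frozen=True)
class FluxResult:
    basal_ra: float = float("nan")
    insulin_rd: float = float("nan")
    egp_basal: float = float("nan")
    egp_clamp: float = float("nan")
    gir_ss: float = float("nan")
    steady_state_window: tuple = (float("nan"), float("nan"))


def tissue_uptake(tissue_dpm: float, tissue_weight_mg: float) -> float:
    """Weight-normalized tissue counts, DPM per mg of initial tissue weight."""
    if tissue_weight_mg <= 0:
        raise ValueError("tissue weight must be positive")
    if tissue_dpm < 0:
        raise ValueError("DPM must be non-negative")
    return tissue_dpm / tissue_weight_mg


def detect_steady_state(
    trace: ClampTrace,
    window_min: float = 15.0,
    gir_cv_max: float = 0.05,
    glucose_tol: float = 0.5,
) -> SteadyState:
    """Find the latest steady-state window of a clamp trace.

    A window qualifies when it spans at least ``window_min`` minutes, the GIR
    coefficient of variation (SD/mean, population SD) is <= ``gir_cv_max``, and
    the mean blood glucose lies within ``glucose_tol`` mM of the target.  The
    search anchors the window end at the latest possible sample and slides it
    earlier until a qualifying window is found; a qualifying window is then
    extended backwards as far as the criteria continue to hold, so a fully
    constant trace yields the full-trace window.  ``gir_ss`` is the mean GIR
    over the selected window.
    """
    t, g, gir = trace.time, trace.glucose, trace.gir
    if t[-1] - t[0] < window_min:
        raise ValueError("trace shorter than the requested window")

    def ok(i: int, j: int) -> bool:
        # window = samples i..j inclusive
        w = gir[i : j + 1]
        m = w.mean()
        if m <= 0:
            return False
        if w.std() / m > gir_cv_max:
            return False
        return abs(g[i : j + 1].mean() - trace.target_glucose) <= glucose_tol

    n = len(t)
    for j in range(n - 1, -1, -1):
        # smallest i giving span >= window_min for this end point
        i0 = int(np.searchsorted(t, t[j] - window_min, side="right")) - 1
        if i0 < 0 or t[j] - t[i0] < window_min:
            break
        if not ok(i0, j):
            continue
        i = i0
        while i > 0 and ok(i - 1, j):
            i -= 1
        w = gir[i : j + 1]
        # exactly constant window: report the constant, not a summed mean
        gir_ss = float(w[0]) if np.ptp(w) == 0 else float(w.mean())
        return SteadyState(True, float(t[i]), float(t[j]), gir_ss)
    return SteadyState(False)


def glucose_turnover(
    tracer_infusion_rate: float, plasma_specific_activity: float
) -> float:
    """Glucose turnover Ra (mg/kg/min) at isotopic steady state.

    Ra = tracer infusion rate (DPM/min per kg) / plasma specific activity
    (DPM per mg glucose).  At basal (GIR = 0) Ra equals EGP; under clamp,
    the disposal rate Rd equals Ra.
    """
    if plasma_specific_activity <= 0:
        raise ValueError("plasma specific activity must be positive")
    return tracer_infusion_rate / plasma_specific_activity


def egp(ra: float, gir: float) -> float:
    """Endogenous glucose production: EGP = Ra - GIR (mg/kg/min).

    Negative results are returned as-is with a warning, so data problems stay
    visible rather than being clipped away.
    """
    value = ra - gir
    if value < 0:
        warnings.warn(f"negative EGP ({value:.3g} mg/kg/min)", stacklevel=2)
    return value


def rg_from_bolus(
    tissue_dpm_per_g: float,
    sample_times: np.ndarray,
    plasma_dpm: np.ndarray,
    plasma_glucose: "float | np.ndarray",
    lumped_constant: float = 1.0,
) -> float:
    """Tissue glucose uptake rate Rg from a 2-DG bolus.

    Rg = tissue phospho-2-DG counts (DPM/g) divided by the integral of plasma
    tracer specific activity SA(t) = plasma_dpm(t)/plasma_glucose(t) over the
    sampling period, integrated by the trapezoid rule on the observed times.
    Units follow the inputs (e.g. DPM/g over DPM/mL/mM/min gives mM*mL/g/min,
    i.e. umol/g/min).  ``lumped_constant`` optionally divides the result for a
    user-supplied 2-DG/glucose discrimination factor (default 1: no
    correction).
    """
    t = np.asarray(sample_times, dtype=float)
    dpm = np.asarray(plasma_dpm, dtype=float)
    glc = np.broadcast_to(np.asarray(plasma_glucose, dtype=float), t.shape)
    if t.size < 3:
        raise ValueError("need at least 3 plasma samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if np.any(glc <= 0):
        raise ValueError("plasma glucose must be positive")
    sa = dpm / glc
    integral = float(np.trapezoid(sa, t))
    if integral <= 0:
        raise ValueError("non-positive specific-activity integral")
    return tissue_dpm_per_g / integral / lumped_constant


def glycolytic_flux(
    sample_dpm: float,
    background_dpm: float,
    medium_specific_activity: float,
    hours: float,
    protein_mg: float,
) -> float:
    """Glycolytic flux in pmol glucose per hour per mg protein.

    Background counts (empty wells) are subtracted and the difference clipped
    at zero (background exceeding sample is counting noise); the result is
    divided by the labelling-medium specific activity (DPM per pmol glucose),
    the incubation time and the protein content.
    """
    if medium_specific_activity <= 0:
        raise ValueError("medium specific activity must be positive")
    if hours <= 0 or protein_mg <= 0:
        raise ValueError("hours and protein must be positive")
    net = max(sample_dpm - background_dpm, 0.0)
    return net / medium_specific_activity / hours / protein_mg


def ecar_metrics(
    ecar: np.ndarray,
    glucose_idx: int,
    oligomycin_idx: int,
    twodg_idx: int,
) -> dict:
    """Glycolysis metrics from an extracellular-acidification-rate series.

    ``*_idx`` give the index of the first measurement after each injection
    (glucose, oligomycin, 2-deoxyglucose).  Definitions:

    * glycolysis = max ECAR after glucose (before oligomycin) - last basal ECAR
    * glycolytic_capacity = max ECAR after oligomycin (before 2-DG) - last basal
    * glycolytic_reserve = capacity - glycolysis
    """
    x = np.asarray(ecar, dtype=float)
    if not 0 < glucose_idx < oligomycin_idx < twodg_idx <= x.size:
        raise ValueError("injection indices must satisfy 0 < glc < oligo < 2dg <= len")
    basal = float(x[glucose_idx - 1])
    post_glc = x[glucose_idx:oligomycin_idx]
    post_oligo = x[oligomycin_idx:twodg_idx]
    if post_glc.size == 0 or post_oligo.size == 0:
        raise ValueError("missing measurement phase")
    glycolysis = float(post_glc.max() - basal)
    capacity = float(post_oligo.max() - basal)
    return {
        "glycolysis": glycolysis,
        "glycolytic_capacity": capacity,
        "glycolytic_reserve": capacity - glycolysis,
    }


def aoc(times: np.ndarray, values: np.ndarray, baseline: "float | None" = None) -> float:
    """Signed area of the curve relative to baseline (default: value at t=0).

    Trapezoidal integral of (value(t) - baseline); excursions above baseline
    contribute positively (glucose tolerance), dips below negatively (insulin
    tolerance), so the sign is informative and is retained.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if baseline is None:
        baseline = float(v[0])
    return float(np.trapezoid(v - baseline, t))
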