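"""Ground-truth-labelled synthetic inputs for every downstream analysis stage.

Three generators, all deterministic under a fixed seed:

* :func:`make_image` renders a two-channel fluorescence field (nuclei channel +
  target-protein channel) of disk-shaped nuclei with cytosolic annuli, a known
  fraction of which carry nuclear-enriched target signal.  The returned truth
  table lists every rendered cell with its center, radius and translocation
  flag, so the image-scoring pipeline can be benchmarked for recovery.
* :func:`make_clamp_trace` produces a basal + clamp glucose-infusion trace with
  an exponential approach of GIR to a plateau at the glycemic target.
* :func:`make_tracer_curve` produces biexponential bolus plasma-decay samples
  plus tissue counts constructed to equal ``true_rg`` times the fine-grid
  integral of plasma specific activity, so the uptake estimator can be tested
  against known rates.

The generators emulate the statistical structure the estimators assume, not
microscope optics or physiology: nuclei are ideal disks without PSF blur or
illumination gradients, clamp noise is white, and the plasma decay is exactly
biexponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .tracer import ClampTrace

__all__ = [
    "ImageSpec",
    "ClampSpec",
    "TracerSpec",
    "PackingError",
    "make_image",
    "make_clamp_trace",
    "make_tracer_curve",
]


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be placed on the canvas."""


@dataclass(frozen=True)
class ImageSpec:
    """Layout and intensity model for a synthetic two-channel field.

    Intensities are arbitrary fluorescence units on a 16-bit scale.  A
    translocated cell is rendered with ``nuclear_intensity_pos`` inside the
    nucleus (target channel); a non-translocated cell with
    ``nuclear_intensity_neg`` (default equal to the cytosol, ratio 1).
    """

    width: int = 1024
    height: int = 1024
    n_cells: int = 200
    nucleus_radius_range: tuple = (6, 10)  # px, inclusive
    translocated_fraction: float = 0.5
    nuclei_intensity: float = 3000.0  # nuclei (DNA-stain) channel
    nuclear_intensity_pos: float = 2500.0  # target channel, translocated
    nuclear_intensity_neg: float = 500.0  # target channel, resident
    cytosol_intensity: float = 500.0
    background_level: float = 100.0
    noise_sd: float = 30.0
    cytosol_width_px: int = 6  # annulus width around each nucleus
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.translocated_fraction <= 1.0:
            raise ValueError("translocated_fraction must be in [0, 1]")
        r_lo, r_hi = self.nucleus_radius_range
        if r_lo < 3 or r_hi < r_lo:
            raise ValueError("radii must satisfy 3 <= r_lo <= r_hi")
        if self.n_cells < 0 or self.width <= 0 or self.height <= 0:
            raise ValueError("invalid canvas or cell count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _pack_disks(spec: ImageSpec, rng: np.random.Generator):
    """Place n_cells disk centers by rejection sampling; nuclei never overlap
    and each cytosolic annulus stays clear of every other nucleus."""
    r_lo, r_hi = spec.nucleus_radius_range
    margin = spec.cytosol_width_px + 2
    centers: list[tuple[float, float]] = []
    radii: list[int] = []
    max_attempts = 300 * max(spec.n_cells, 1) + 1000
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(centers)}/{spec.n_cells} cells after "
                f"{max_attempts} attempts; canvas too small"
            )
        attempts += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        pad = r + spec.cytosol_width_px + 1
        if spec.width <= 2 * pad or spec.height <= 2 * pad:
            raise PackingError("canvas smaller than a single cell footprint")
        cx = float(rng.uniform(pad, spec.width - pad))
        cy = float(rng.uniform(pad, spec.height - pad))
        if all(
            (cx - x) ** 2 + (cy - y) ** 2 >= (r + rr + margin) ** 2
            for (x, y), rr in zip(centers, radii)
        ):
            centers.append((cx, cy))
            radii.append(r)
    return centers, radii


def make_image(spec: ImageSpec):
    """Render one synthetic field.

    Returns ``(nuclei_channel, target_channel, truth)`` where the channels are
    uint16 arrays of shape (height, width) and ``truth`` is a DataFrame with
    columns cell_id, cx, cy, radius, translocated.  Exactly
    ``round(translocated_fraction * n_cells)`` cells are flagged translocated;
    the assignment of flags to positions is shuffled by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    nuclei = np.full(shape, spec.background_level, dtype=float)
    target = np.full(shape, spec.background_level, dtype=float)

    centers, radii = _pack_disks(spec, rng)
    n = len(centers)
    k = int(round(spec.translocated_fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)

    # cytosolic annuli first so nuclear disks overwrite any overlap
    for (cx, cy), r in zip(centers, radii):
        rr, cc = draw_disk((cy, cx), r + spec.cytosol_width_px, shape=shape)
        target[rr, cc] = spec.cytosol_intensity
    for (cx, cy), r, pos in zip(centers, radii, flags):
        rr, cc = draw_disk((cy, cx), r, shape=shape)
        nuclei[rr, cc] = spec.nuclei_intensity
        target[rr, cc] = spec.nuclear_intensity_pos if pos else spec.nuclear_intensity_neg

    if spec.noise_sd > 0:
        nuclei += rng.normal(0.0, spec.noise_sd, shape)
        target += rng.normal(0.0, spec.noise_sd, shape)

    nuclei_u16 = np.clip(np.rint(nuclei), 0, 65535).astype(np.uint16)
    target_u16 = np.clip(np.rint(target), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "cx": [c[0] for c in centers],
            "cy": [c[1] for c in centers],
            "radius": radii,
            "translocated": flags,
        }
    )
    return nuclei_u16, target_u16, truth


@dataclass(frozen=True)
class ClampSpec:
    """Model for a basal + hyperinsulinemic-euglycemic clamp trace.

    During the basal phase GIR is zero and glucose sits at ``basal_glucose``
    (default: the clamp target, 6 mM).  During the clamp, GIR approaches
    ``plateau_gir`` exponentially at ``approach_rate`` and glucose relaxes to
    ``target_glucose``.  ``approach_rate=inf`` gives a flat plateau from the
    first clamp sample.
    """

    basal_duration: float = 80.0  # min
    clamp_duration: float = 90.0  # min
    target_glucose: float = 6.0  # mM
    plateau_gir: float = 36.3  # mg/kg/min
    approach_rate: float = 0.15  # 1/min
    sampling_interval: float = 2.5  # min
    basal_glucose: float | None = None
    glucose_noise_sd: float = 0.15  # mM
    gir_noise_sd: float = 0.8  # mg/kg/min
    insulin_infusion: float = 12.0  # mU/kg/min
    seed: int = 0

    def __post_init__(self):
        if self.basal_duration < 0 or self.clamp_duration <= 0:
            raise ValueError("durations must be positive")
        if self.plateau_gir < 0 or self.target_glucose <= 0:
            raise ValueError("plateau_gir >= 0 and target_glucose > 0 required")
        if self.sampling_interval <= 0 or self.approach_rate <= 0:
            raise ValueError("sampling_interval and approach_rate must be positive")
        if self.glucose_noise_sd < 0 or self.gir_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def make_clamp_trace(spec: ClampSpec) -> ClampTrace:
    """Simulate one clamp trace on a regular sampling grid."""
    rng = np.random.default_rng(spec.seed)
    total = spec.basal_duration + spec.clamp_duration
    t = np.arange(0.0, total + 0.5 * spec.sampling_interval, spec.sampling_interval)
    basal_glc = spec.target_glucose if spec.basal_glucose is None else spec.basal_glucose

    clamp_phase = t >= spec.basal_duration
    dt = np.where(clamp_phase, t - spec.basal_duration, 0.0)
    if np.isinf(spec.approach_rate):
        rise = np.ones_like(t)
    else:
        rise = 1.0 - np.exp(-spec.approach_rate * dt)
    gir = np.where(clamp_phase, spec.plateau_gir * rise, 0.0)
    glucose = np.where(
        clamp_phase,
        spec.target_glucose + (basal_glc - spec.target_glucose) * (1.0 - rise),
        basal_glc,
    )
    if spec.gir_noise_sd > 0:
        gir = gir + np.where(clamp_phase, rng.normal(0, spec.gir_noise_sd, t.shape), 0.0)
        gir = np.clip(gir, 0.0, None)
    if spec.glucose_noise_sd > 0:
        glucose = glucose + rng.normal(0, spec.glucose_noise_sd, t.shape)
    return ClampTrace(
        time=t,
        glucose=glucose,
        gir=gir,
        insulin_infusion=spec.insulin_infusion,
        target_glucose=spec.target_glucose,
    )


@dataclass(frozen=True)
class TracerSpec:
    """Biexponential bolus plasma decay plus tissue accumulation.

    Plasma tracer follows A1*exp(-k1 t) + A2*exp(-k2 t) (DPM/mL).  The default
    rate constants correspond to distribution and clearance half-lives of
    roughly 10 and 35 min, typical of a 2-deoxyglucose bolus in the mouse.
    Tissue counts are constructed as true_rg x integral of plasma specific
    activity (fine-grid trapezoid, dt = 0.01 min), so an estimator that divides
    tissue counts by its own integral of the *sampled* curve can be scored for
    recovery of ``true_rg``.
    """

    a1: float = 60000.0  # DPM/mL
    k1: float = 0.07  # 1/min
    a2: float = 30000.0  # DPM/mL
    k2: float = 0.02  # 1/min
    sample_times: tuple = (0.0, 2.0, 15.0, 25.0, 35.0)  # min
    true_rg: dict = field(default_factory=lambda: {"iWAT": 0.5})  # per-tissue rate
    plasma_glucose: float = 6.0  # mM, constant under clamp
    noise_frac: float = 0.005  # multiplicative measurement noise
    seed: int = 0

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("decay rates must be non-negative")
        st = np.asarray(self.sample_times, dtype=float)
        if st[0] != 0 or np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must start at 0 and strictly increase")
        if self.plasma_glucose <= 0:
            raise ValueError("plasma_glucose must be positive")
        if any(v < 0 for v in self.true_rg.values()):
            raise ValueError("true_rg must be non-negative")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be non-negative")


def _plasma_model(spec: TracerSpec, t: np.ndarray) -> np.ndarray:
    return spec.a1 * np.exp(-spec.k1 * t) + spec.a2 * np.exp(-spec.k2 * t)


def make_tracer_curve(spec: TracerSpec):
    """Simulate bolus plasma samples and consistent tissue counts.

    Returns ``(plasma, tissue)`` DataFrames.  ``plasma`` has columns time,
    plasma_dpm, plasma_glucose; ``tissue`` has columns tissue, true_rg,
    tissue_dpm_per_g.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sample_times, dtype=float)
    dpm = _plasma_model(spec, t)
    if spec.noise_frac > 0:
        dpm = dpm * (1.0 + rng.normal(0, spec.noise_frac, t.shape))
    plasma = pd.DataFrame(
        {"time": t, "plasma_dpm": dpm, "plasma_glucose": spec.plasma_glucose}
    )

    grid = np.arange(0.0, t[-1] + 1e-9, 0.01)
    sa_integral = float(np.trapezoid(_plasma_model(spec, grid) / spec.plasma_glucose, grid))
    rows = []
    for tissue, rg in spec.true_rg.items():
        counts = rg * sa_integral
        if spec.noise_frac > 0:
            counts *= 1.0 + rng.normal(0, spec.noise_frac)
        rows.append({"tissue": tissue, "true_rg": rg, "tissue_dpm_per_g": counts})
    return plasma, pd.DataFrame(rows)
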