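"""Molecular-formula mass arithmetic and external-standard quantification.

This module backs compound-identity bookkeeping for high-resolution ESI-MS:
parsing Hill-notation molecular formulas, computing monoisotopic masses and
adduct m/z values, expressing mass accuracy as a ppm error, and quantifying an
analyte against an external calibration line (peak area vs. concentration).

Ionization convention
---------------------
Published "calculated" m/z values in natural-product characterization are
frequently quoted for the *ion* composition (the formula as printed already
includes the gained/lost proton).  Two conventions coexist for the electron:

* ``exact=False`` (default): negative-mode m/z is the plain formula mass of the
  deprotonated composition (no electron-mass correction); positive-mode m/z is
  the formula mass of the protonated composition minus one electron mass.  This
  asymmetric handling matches common practice in phytochemistry reports.
* ``exact=True``: the electron mass is added in negative mode and subtracted in
  positive mode, i.e. the physically exact ion mass in both polarities.

Monoisotopic atomic masses are pinned as module constants so results are
bit-stable across platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "H_ATOM_MASS",
    "MolecularFormula",
    "CalibrationCurve",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "fit_calibration",
    "quantify",
]

#: Monoisotopic atomic masses in Da (CODATA/IUPAC values, pinned).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

ELECTRON_MASS = 0.000549  # Da
PROTON_MASS = 1.007276  # Da
H_ATOM_MASS = 1.007825  # Da

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with a canonical Hill string form."""

    counts: tuple[tuple[str, int], ...]

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        d = self.as_dict
        parts: list[str] = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if el in d:
                n = d[el]
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.as_dict
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return MolecularFormula(tuple(sorted(d.items())))


def parse_formula(text: str) -> MolecularFormula:
    """Parse a plain Hill-notation formula such as ``"C19H17O11"``.

    Isotope labels, charges and parentheses are not supported.  Raises
    :class:`FormulaError` with the offending position on malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unexpected character at position {pos}: {text[pos]!r}")
        if not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {el!r} at position {m.start()}")
        n = int(num) if num else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {el} at position {m.start()}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unexpected character at position {pos}: {text[pos]!r}")
    if not counts:
        raise FormulaError("empty formula")
    return MolecularFormula(tuple(sorted(counts.items())))


def _as_formula(formula: "MolecularFormula | str") -> MolecularFormula:
    return formula if isinstance(formula, MolecularFormula) else parse_formula(formula)


def monoisotopic_mass(formula: "MolecularFormula | str") -> float:
    """Full-precision monoisotopic mass (Da) of a formula."""
    f = _as_formula(formula)
    return float(sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts))


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def adduct_mz(
    ion_formula: "MolecularFormula | str",
    mode: str,
    exact: bool = False,
    ndigits: int | None = 4,
) -> float:
    """m/z of a singly charged ion whose *ion composition* is ``ion_formula``.

    Parameters
    ----------
    ion_formula
        The composition of the ion as printed, i.e. already including the
        gained proton for ``[M+H]+`` or excluding the lost one for ``[M-H]-``.
    mode
        ``"pos"`` or ``"neg"``.
    exact
        Apply the electron-mass correction symmetrically (see module docstring).
    ndigits
        Decimal places for half-up rounding of the result; ``None`` returns the
        full-precision value.
    """
    if mode not in ("pos", "neg"):
        raise ValueError(f"mode must be 'pos' or 'neg', got {mode!r}")
    mz = monoisotopic_mass(ion_formula)
    if mode == "pos":
        mz -= ELECTRON_MASS
    elif exact:
        mz += ELECTRON_MASS
    return mz if ndigits is None else _round_half_up(mz, ndigits)


def ppm_error(observed_mz: float, calculated_mz: float, ndigits: int | None = 1) -> float:
    """Relative mass error (observed - calculated)/calculated * 1e6 in ppm.

    Rounded half away from zero at ``ndigits`` decimals (``None`` = no rounding).
    """
    if calculated_mz <= 0:
        raise ValueError("calculated_mz must be positive")
    ppm = (observed_mz - calculated_mz) / calculated_mz * 1e6
    return ppm if ndigits is None else _round_half_up(ppm, ndigits)


@dataclass(frozen=True)
class CalibrationCurve:
    """External-standard calibration line: area = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float = field(default=float("nan"))
    conc_max: float = field(default=float("nan"))

    def concentration(self, area: float) -> float:
        """Invert the line: analyte concentration for a peak area."""
        if self.slope == 0:
            raise ValueError("calibration slope is zero; cannot invert")
        return (area - self.intercept) / self.slope

    def in_range(self, conc: float) -> bool:
        if np.isnan(self.conc_min) or np.isnan(self.conc_max):
            return True
        return self.conc_min <= conc <= self.conc_max


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least squares fit of (concentration, peak area) pairs.

    ``points`` is an iterable of ``(conc, area)``; at least two distinct
    concentrations are required.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (conc, area) points")
    conc, area = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations identical; slope undefined")
    res = stats.linregress(conc, area)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
    )


def quantify(
    area: float,
    curve: CalibrationCurve,
    sample_conc_mg_ml: float,
    dilution: float = 1.0,
) -> dict:
    """Percent (w/w) of an analyte in a sample from its peak area.

    The calibration line is in µg/mL vs. area; the sample is weighed in at
    ``sample_conc_mg_ml`` (mg dry material per mL) and optionally diluted by
    ``dilution`` before injection.  Returns a dict with the back-calculated
    analyte concentration (µg/mL), the %% w/w, and an ``extrapolated`` flag set
    when the area falls outside the calibrated concentration range.
    """
    if sample_conc_mg_ml <= 0:
        raise ValueError("sample concentration must be positive")
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    analyte_ug_ml = curve.concentration(area)
    sample_ug_ml = sample_conc_mg_ml * 1000.0 * dilution
    pct_ww = analyte_ug_ml / sample_ug_ml * 100.0
    return {
        "analyte_conc_ug_ml": analyte_ug_ml,
        "pct_ww": pct_ww,
        "extrapolated": not curve.in_range(analyte_ug_ml),
    }
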