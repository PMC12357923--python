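"""Interspecies dose translation and diet-admixture arithmetic.

Human-equivalent dosing follows the FDA body-surface-area convention: doses in
mg/kg scale between species by the ratio of their Km factors (body weight /
surface area), Km = 37 for an adult human and 3 for a mouse.  A human intake of
10.5 mg/kg/day therefore corresponds to 10.5 x 37/3 ~= 130 mg/kg/day in the
mouse after rounding to the nearest 10 mg/kg.

Fraction/compound apportionment converts a parent-extract dose into doses of
chromatographic fractions (stated as % of the extract) and of individual
constituents (stated as % of their parent fraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "KM_HUMAN",
    "KM_MOUSE",
    "DoseSpec",
    "FractionPlan",
    "hed_animal_dose",
    "human_dose_from_animal",
    "diet_admixture",
    "apportion",
]

KM_HUMAN = 37.0
KM_MOUSE = 3.0


@dataclass(frozen=True)
class DoseSpec:
    """Parameters for human-to-animal dose scaling.

    ``rounding_mg_kg``: granularity for rounding the animal dose (half-up);
    0 disables rounding.
    """

    human_dose: float  # mg/kg/day
    km_human: float = KM_HUMAN
    km_animal: float = KM_MOUSE
    body_weight: float = 0.030  # kg, adult mouse
    daily_intake: float = 3.0  # g food/day
    rounding_mg_kg: float = 10.0

    def __post_init__(self):
        if self.human_dose < 0:
            raise ValueError("human_dose must be non-negative")
        if self.km_human <= 0 or self.km_animal <= 0:
            raise ValueError("Km factors must be positive")
        if self.body_weight <= 0 or self.daily_intake <= 0:
            raise ValueError("body_weight and daily_intake must be positive")


@dataclass(frozen=True)
class FractionPlan:
    """Extract dose plus fraction / constituent proportions.

    ``fraction_pct`` maps fraction name -> % of the parent extract;
    ``compound_pct`` maps constituent name -> % of ``compound_parent``
    (one of the fractions).
    """

    extract_dose: float  # mg/kg
    fraction_pct: dict[str, float] = field(default_factory=dict)
    compound_pct: dict[str, float] = field(default_factory=dict)
    compound_parent: str | None = None

    def __post_init__(self):
        if self.extract_dose < 0:
            raise ValueError("extract_dose must be non-negative")
        for name, pct in {**self.fraction_pct, **self.compound_pct}.items():
            if not 0 < pct <= 100:
                raise ValueError(f"proportion for {name!r} must be in (0, 100]")
        if self.compound_pct and self.compound_parent not in self.fraction_pct:
            raise ValueError("compound_parent must name one of the fractions")


def _round_to(value: float, granularity: float) -> float:
    if granularity <= 0:
        return value
    q = Decimal(repr(value)) / Decimal(repr(granularity))
    return float(q.quantize(Decimal(1), rounding=ROUND_HALF_UP) * Decimal(repr(granularity)))


def hed_animal_dose(spec: DoseSpec) -> float:
    """Animal dose (mg/kg/day) from a human dose via BSA Km scaling."""
    dose = spec.human_dose * spec.km_human / spec.km_animal
    return _round_to(dose, spec.rounding_mg_kg)


def human_dose_from_animal(animal_dose: float, km_human: float = KM_HUMAN,
                           km_animal: float = KM_MOUSE) -> float:
    """Inverse scaling (unrounded): human dose implied by an animal dose."""
    return animal_dose * km_animal / km_human


def diet_admixture(dose_mg_kg_day: float, body_weight_kg: float,
                   daily_intake_g: float) -> float:
    """mg of compound per g of diet delivering ``dose_mg_kg_day``.

    concentration = dose x body_weight / daily_intake.
    """
    if daily_intake_g <= 0:
        raise ValueError("daily_intake must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body_weight must be positive")
    return dose_mg_kg_day * body_weight_kg / daily_intake_g


def apportion(plan: FractionPlan) -> dict[str, float]:
    """Per-fraction and per-constituent doses (mg/kg) from stated proportions.

    Fraction doses are proportions of the extract dose; constituent doses are
    proportions of their parent fraction's dose.  A warning is emitted if the
    proportions at either level sum past 100%.
    """
    for level, d in (("fraction", plan.fraction_pct), ("compound", plan.compound_pct)):
        total = sum(d.values())
        if total > 100.0 + 1e-9:
            warnings.warn(f"{level} proportions sum to {total:.1f}% > 100%", stacklevel=2)
    doses = {name: pct / 100.0 * plan.extract_dose for name, pct in plan.fraction_pct.items()}
    if plan.compound_pct:
        parent_dose = doses[plan.compound_parent]
        for name, pct in plan.compound_pct.items():
            doses[name] = pct / 100.0 * parent_dose
    return doses
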