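"""Small QC statistics: Grubbs single-outlier test, delta-delta-Ct relative
expression, percent change, and mean +/- SD/SEM summaries.

The Grubbs test flags at most one observation per call: the point with the
largest studentized deviation G = max|x_i - mean| / s is declared an outlier
when G exceeds the two-sided critical value

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)),

with t the upper alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
An iterative mode repeats the test on the reduced sample; it is off by default
because repeated testing inflates the type-I error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OutlierResult",
    "ExpressionResult",
    "grubbs",
    "grubbs_critical",
    "ddct",
    "percent_change",
    "summarize",
]


@dataclass(frozen=True)
class OutlierResult:
    index: int | None  # index of the flagged value, or None
    g: float  # observed G statistic
    critical: float  # two-sided critical value at alpha
    alpha: float

    @property
    def is_outlier(self) -> bool:
        return self.index is not None


@dataclass(frozen=True)
class ExpressionResult:
    delta_ct_sample: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at ``alpha``."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs(values, alpha: float = 0.05) -> OutlierResult:
    """Two-sided single-pass Grubbs test.

    Returns the index of the most extreme value if its studentized deviation
    exceeds the critical value, else ``index=None``.  Requires n >= 3 finite
    values with nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance; Grubbs statistic undefined")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / s)
    crit = grubbs_critical(x.size, alpha)
    return OutlierResult(index=i if g > crit else None, g=g, critical=crit, alpha=alpha)


def grubbs_remove(values, alpha: float = 0.05, iterative: bool = False):
    """Return (cleaned array, list of OutlierResult for each removal).

    With ``iterative=True`` the test is reapplied after each removal until no
    outlier is found (logged with a warning about inflated type-I error).
    """
    x = np.asarray(values, dtype=float)
    removed: list[OutlierResult] = []
    if iterative:
        warnings.warn(
            "iterative Grubbs removal inflates the type-I error rate", stacklevel=2
        )
    while x.size >= 3:
        res = grubbs(x, alpha)
        if not res.is_outlier:
            break
        removed.append(res)
        x = np.delete(x, res.index)
        if not iterative:
            break
    return x, removed


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> ExpressionResult:
    """Relative expression by the delta-delta-Ct method.

    deltaCt = Ct(target) - Ct(reference housekeeping gene), per condition;
    deltadeltaCt = deltaCt(sample) - deltaCt(control); fold = 2**(-ddCt).
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    d_s = ct_target_sample - ct_ref_sample
    d_c = ct_target_control - ct_ref_control
    dd = d_s - d_c
    return ExpressionResult(
        delta_ct_sample=d_s,
        delta_ct_control=d_c,
        delta_delta_ct=dd,
        fold_change=2.0 ** (-dd),
    )


def percent_change(treated: float, control: float) -> float:
    """Signed percent decrease of ``treated`` relative to ``control``.

    100 * (control - treated) / control: positive for a decrease, negative for
    an increase.
    """
    if control == 0:
        raise ValueError("control value must be nonzero")
    return 100.0 * (control - treated) / control


def summarize(values, mode: str = "SEM") -> dict:
    """Mean and dispersion (``mode`` = ``"SEM"`` or ``"SD"``, n-1 denominator).

    With a single value the dispersion is returned as NaN.
    """
    if mode not in ("SEM", "SD"):
        raise ValueError("mode must be 'SEM' or 'SD'")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a non-empty 1-D sample")
    n = x.size
    mean = float(x.mean())
    if n < 2:
        disp = float("nan")
    else:
        sd = float(x.std(ddof=1))
        disp = sd / math.sqrt(n) if mode == "SEM" else sd
    return {"mean": mean, "dispersion": disp, "mode": mode, "n": n}
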