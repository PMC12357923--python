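"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: pixel sets are built
from explicit city-block distance computations rather than morphological
iteration, and the Student-t quantile is obtained by bisection on the
incomplete-beta CDF rather than scipy.stats.t.ppf.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betainc


def _l1_distance_to(shape, source_mask):
    """Min city-block distance from every pixel to a source set (inf if empty)."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    sy, sx = np.nonzero(source_mask)
    if sy.size == 0:
        return np.full(shape, np.inf)
    d = np.abs(ys.ravel()[:, None] - sy[None, :]) + np.abs(xs.ravel()[:, None] - sx[None, :])
    return d.min(axis=1).reshape(shape).astype(float)


def brute_force_measure(labels, target, mask, erosion_px=1, gap_px=1, width_px=3):
    """Per-nucleus (core_mean, ring_mean) by explicit pixel enumeration.

    Returns dict label -> (nuclear_mean, ring_mean, core_set, ring_set); labels
    whose core or masked ring is empty are omitted.  Only valid for nuclei that
    do not touch the image border.
    """
    labels = np.asarray(labels)
    target = np.asarray(target, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = {}
    # every relevant pixel for one nucleus lies within gap+width of it, and any
    # interfering neighbour nucleus within a further gap, so a padded bounding
    # box sees everything the full frame would
    pad = 2 * gap_px + width_px + 1
    for lab in np.unique(labels[labels > 0]):
        ys, xs = np.nonzero(labels == lab)
        y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, labels.shape[0])
        x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, labels.shape[1])
        win = np.s_[y0:y1, x0:x1]
        lab_w, tgt_w, mask_w = labels[win], target[win], mask[win]
        shape = lab_w.shape
        nuc = lab_w == lab
        # erosion: keep pixels farther than erosion_px from the complement
        d_out = _l1_distance_to(shape, ~nuc)
        core = nuc & (d_out > erosion_px)
        # ring: band gap < d <= gap+width around this nucleus, inside the cell
        # mask, clear of every nucleus dilated by the gap
        d_this = _l1_distance_to(shape, nuc)
        d_any = _l1_distance_to(shape, lab_w > 0)
        ring = (d_this > gap_px) & (d_this <= gap_px + width_px) & mask_w & (d_any > gap_px)
        if not core.any() or not ring.any():
            continue
        core_full = np.zeros(labels.shape, dtype=bool)
        ring_full = np.zeros(labels.shape, dtype=bool)
        core_full[win], ring_full[win] = core, ring
        out[int(lab)] = (
            float(tgt_w[core].mean()),
            float(tgt_w[ring].mean()),
            core_full,
            ring_full,
        )
    return out


def t_quantile(p, df, tol=1e-12):
    """Upper-tail-free Student-t quantile via bisection on the betainc CDF."""

    def cdf(t):
        if t == 0:
            return 0.5
        x = df / (df + t * t)
        tail = 0.5 * betainc(df / 2.0, 0.5, x)
        return 1.0 - tail if t > 0 else tail

    lo, hi = -1e8, 1e8
    while hi - lo > tol * max(1.0, abs(lo), abs(hi)):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def grubbs_critical_oracle(n, alpha):
    """Closed-form two-sided Grubbs critical value from the t quantile."""
    t = t_quantile(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
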