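"""Agreement statistics between predicted values/ranges and measured
ranges (flux within 1 s.d., interval-overlap fractions)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mm_convert import IntervalRange, range_overlap


def fraction_within(predicted, lower, upper) -> float:
    """Percentage of predictions inside their closed [lower, upper] range."""
    p = np.asarray(predicted, dtype=float)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if not (len(p) == len(lo) == len(hi)):
        raise ValueError("length mismatch")
    if len(p) == 0:
        raise ValueError("empty comparison")
    ok = (p >= lo) & (p <= hi)
    return 100.0 * float(np.mean(ok))


def flux_within_sd_pct(table: pd.DataFrame) -> float:
    """Percentage of predicted fluxes within the 1-s.d. measured range.

    Expects columns ``predicted``, ``mean`` and ``sd``.
    """
    lo = table["mean"] - table["sd"]
    hi = table["mean"] + table["sd"]
    return fraction_within(table["predicted"], lo, hi)


def overlap_fraction_pct(table: pd.DataFrame) -> float:
    """Percentage of rows whose predicted and measured closed intervals
    intersect.

    Expects columns ``predicted_lo``, ``predicted_hi``, ``measured_lo``
    and ``measured_hi``.
    """
    if len(table) == 0:
        raise ValueError("empty comparison")
    hits = [range_overlap(IntervalRange(plo, phi), IntervalRange(mlo, mhi))
            for plo, phi, mlo, mhi in zip(table["predicted_lo"],
                                          table["predicted_hi"],
                                          table["measured_lo"],
                                          table["measured_hi"])]
    return 100.0 * float(np.mean(hits))


def point_overlap_pct(table: pd.DataFrame, halfwidth: float = 0.10) -> float:
    """Overlap percentage for point predictions: each ``predicted`` value is
    wrapped in a +/- *halfwidth* relative range before the interval test."""
    t = table.copy()
    lo = t["predicted"] * (1.0 - halfwidth)
    hi = t["predicted"] * (1.0 + halfwidth)
    t["predicted_lo"] = np.minimum(lo, hi)
    t["predicted_hi"] = np.maximum(lo, hi)
    return overlap_fraction_pct(t)
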