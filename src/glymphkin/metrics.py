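"""Model-free glymphatic summary metrics from normalized ROI curves.

Given a normalized concentration time-course Gd(t) with baseline Gd_pre,
peak Gd_max at time TTP and value Gd_300 at 300 min:

    wash-in rate   = (Gd_max - Gd_pre) / TTP
    washout rate   = (0.9 Gd_max - 0.1 Gd_max) / (t_10% - t_90%)
    retention(%)   = 100 (Gd_300 - Gd_pre) / (Gd_max - Gd_pre)

t_90% and t_10% are the first post-peak times at which the curve crosses
90% and 10% of the peak, located by linear interpolation between samples;
if the 10% level is never reached inside the observation window the
terminal linear segment is extrapolated to the crossing and the result is
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GlymphaticMetrics",
    "time_to_peak",
    "wash_in_rate",
    "wash_out_rate",
    "retention_ratio",
    "compute_all_metrics",
]


@dataclass
class GlymphaticMetrics:
    gd_pre: float
    gd_max: float
    gd_300: float
    ttp_min: float
    wash_in_rate: float
    wash_out_rate: float
    retention_ratio_pct: float
    flags: set = field(default_factory=set)


def _as_curve(times_min, values):
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size == 0:
        raise ValueError("empty curve")
    if t.shape != y.shape:
        raise ValueError("times and values must match")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, y


def time_to_peak(times_min, values) -> tuple[float, float, set]:
    """Time of the global maximum (ties -> earliest) and the peak value.

    Returns ``(ttp_min, gd_max, flags)``; a peak at the final sample is
    flagged ``no_decay``.
    """
    t, y = _as_curve(times_min, values)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    idx = int(np.argmax(y))  # argmax takes the first of tied maxima
    flags = {"no_decay"} if idx == t.size - 1 else set()
    return float(t[idx]), float(y[idx]), flags


def wash_in_rate(times_min, values) -> float:
    """Baseline-to-peak slope (Gd_max - Gd_pre) / TTP."""
    t, y = _as_curve(times_min, values)
    ttp, gd_max, _ = time_to_peak(t, y)
    gd_pre = y[0]
    if gd_max <= gd_pre:
        raise ValueError("flat or non-enhancing curve: wash-in undefined")
    if ttp <= t[0]:
        raise ValueError("peak at baseline: wash-in undefined")
    return (gd_max - gd_pre) / (ttp - t[0])


def _first_crossing(t, y, level, start_idx):
    """First time at/after ``start_idx`` where y falls to ``level`` (linear interp)."""
    for i in range(start_idx, t.size - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 >= level >= y1 and y0 != y1:
            return t[i] + (y0 - level) / (y0 - y1) * (t[i + 1] - t[i])
        if y0 == level:
            return float(t[i])
    return None


def wash_out_rate(times_min, values) -> tuple[float, set]:
    """90%-to-10%-of-peak decay slope; returns ``(rate, flags)``.

    ``rate = 0.8 Gd_max / (t_10% - t_90%)``.  Crossings not reached within
    the window are obtained by extrapolating the terminal linear segment
    (flag ``washout_extrapolated``); a post-peak curve that does not decay
    at all yields NaN with flag ``no_decay``.
    """
    t, y = _as_curve(times_min, values)
    ttp, gd_max, peak_flags = time_to_peak(t, y)
    flags = set(peak_flags)
    peak_idx = int(np.argmax(y))
    if peak_idx >= t.size - 1 or not np.any(y[peak_idx + 1 :] < y[peak_idx]):
        flags.add("no_decay")
        return float("nan"), flags
    term_slope = (y[-1] - y[-2]) / (t[-1] - t[-2])

    def crossing(level):
        c = _first_crossing(t, y, level, peak_idx)
        if c is not None:
            return c, False
        if term_slope >= 0:
            return None, False
        return t[-1] + (level - y[-1]) / term_slope, True

    t90, ex90 = crossing(0.9 * gd_max)
    t10, ex10 = crossing(0.1 * gd_max)
    if t90 is None or t10 is None or t10 <= t90:
        flags.add("no_decay")
        return float("nan"), flags
    if ex90 or ex10:
        flags.add("washout_extrapolated")
    return 0.8 * gd_max / (t10 - t90), flags


def retention_ratio(times_min, values, t_eval_min: float = 300.0) -> tuple[float, set]:
    """Percent of peak enhancement remaining at ``t_eval_min``.

    ``100 (Gd(t_eval) - Gd_pre) / (Gd_max - Gd_pre)``; the evaluation point
    is linearly interpolated (flag ``t300_missing``) if not sampled.
    """
    t, y = _as_curve(times_min, values)
    _, gd_max, _ = time_to_peak(t, y)
    gd_pre = y[0]
    if gd_max <= gd_pre:
        raise ValueError("flat curve: retention ratio undefined")
    if not t[0] <= t_eval_min <= t[-1]:
        raise ValueError(f"t_eval {t_eval_min} outside observed range [{t[0]}, {t[-1]}]")
    flags = set()
    if not np.any(np.isclose(t, t_eval_min)):
        flags.add("t300_missing")
    g_eval = float(np.interp(t_eval_min, t, y))
    return 100.0 * (g_eval - gd_pre) / (gd_max - gd_pre), flags


def curve_metrics(times_min, values, t_eval_min: float = 300.0) -> GlymphaticMetrics:
    """All scalar metrics for one curve, with flags propagated."""
    t, y = _as_curve(times_min, values)
    ttp, gd_max, flags = time_to_peak(t, y)
    gd_pre = float(y[0])
    t_eval = min(t_eval_min, t[-1])
    if t_eval != t_eval_min:
        flags.add("t300_missing")
    try:
        wi = wash_in_rate(t, y)
    except ValueError:
        wi, flags = float("nan"), flags | {"flat_curve"}
    wo, wo_flags = wash_out_rate(t, y)
    flags |= wo_flags
    if gd_max > gd_pre:
        ret, ret_flags = retention_ratio(t, y, t_eval)
        flags |= ret_flags
    else:
        ret = float("nan")
    return GlymphaticMetrics(
        gd_pre=gd_pre,
        gd_max=gd_max,
        gd_300=float(np.interp(t_eval, t, y)),
        ttp_min=ttp,
        wash_in_rate=wi,
        wash_out_rate=wo,
        retention_ratio_pct=ret,
        flags=flags,
    )


def compute_all_metrics(conc_series, region_masks: dict, t_eval_min: float = 300.0) -> pd.DataFrame:
    """One metrics row per region (e.g. whole brain, cortex, hippocampus)."""
    from .concentration import roi_timecourse

    if not region_masks:
        raise ValueError("empty region list")
    rows = []
    for label, mask in region_masks.items():
        tsc = roi_timecourse(conc_series, mask)
        m = curve_metrics(conc_series.times_min, tsc, t_eval_min)
        rows.append(
            {
                "region": label,
                "gd_pre": m.gd_pre,
                "gd_max": m.gd_max,
                "gd_300": m.gd_300,
                "ttp_min": m.ttp_min,
                "wash_in_rate": m.wash_in_rate,
                "wash_out_rate": m.wash_out_rate,
                "retention_ratio_pct": m.retention_ratio_pct,
                "flags": ",".join(sorted(m.flags)),
            }
        )
    return pd.DataFrame(rows).set_index("region")


__all__.append("curve_metrics")
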