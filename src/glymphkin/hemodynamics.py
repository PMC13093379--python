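"""Pulsatility/resistance indices from laser-speckle flow waveforms, and
background-corrected intravascular efflux time courses.

Per-waveform indices follow the Doppler-style definitions

    PI = (peak systolic flow - end diastolic flow) / mean flow
    RI = (peak systolic flow - end diastolic flow) / peak systolic flow.

Cardiac cycles are detected by peak finding; by default the indices are
extracted from an ensemble-averaged beat (cycles phase-aligned on
sub-sample-refined systolic peaks and averaged), which suppresses the
order-statistic bias that raw per-cycle extrema acquire under measurement
noise.  Raw per-cycle and whole-trace ("global") modes are also available;
the per-cycle table always accompanies the result, and there the identity
RI = PI * mean / systolic holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FlowWaveform",
    "HemodynamicIndices",
    "EffluxSeries",
    "detect_cycles",
    "pulsatility_index",
    "resistance_index",
    "flow_indices",
    "efflux_timecourse",
    "roi_mean_from_image",
]


@dataclass
class FlowWaveform:
    """Uniformly sampled flow trace (arbitrary perfusion units)."""

    values: np.ndarray
    fs_hz: float = 120.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("waveform must be a 1-D array with >= 2 samples")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs_hz


@dataclass
class HemodynamicIndices:
    pi: float
    ri: float
    n_cycles: int
    per_cycle: pd.DataFrame = field(repr=False, default=None)
    pi_sd: float = float("nan")
    ri_sd: float = float("nan")
    mode: str = "ensemble"


@dataclass
class EffluxSeries:
    times_min: np.ndarray
    vessel_intensity: np.ndarray
    background_intensity: np.ndarray

    @property
    def corrected_intensity(self) -> np.ndarray:
        return self.vessel_intensity - self.background_intensity


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def _parabolic_vertex(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum location/value via a 3-point quadratic fit."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    return i + d, b - 0.25 * (a - c) * d


def detect_cycles(
    waveform: FlowWaveform,
    hr_range_hz: tuple[float, float] = (3.0, 15.0),
    prominence_frac: float = 0.3,
) -> np.ndarray:
    """Systolic-peak indices; cycles are the peak-to-peak intervals.

    Peaks are found on a lightly smoothed copy with a minimum inter-peak
    distance of fs/hr_max and a prominence of ``prominence_frac`` times the
    (smoothed) waveform range.  Deterministic.  Raises if no peaks emerge
    (e.g. a constant trace).
    """
    hr_lo, hr_hi = hr_range_hz
    if waveform.duration_s * hr_lo < 2:
        raise ValueError("waveform shorter than two expected cycles")
    window = max(3, int(round(waveform.fs_hz / hr_hi / 2)) | 1)
    smoothed = _smooth(waveform.values, window)
    rng = float(np.ptp(smoothed))
    if rng == 0:
        raise ValueError("no peaks found: constant waveform")
    distance = max(1, int(waveform.fs_hz / hr_hi))
    peaks, _ = find_peaks(smoothed, distance=distance, prominence=prominence_frac * rng)
    if peaks.size < 2:
        raise ValueError("no peaks found: fewer than two systolic peaks detected")
    if waveform.fs_hz / hr_hi < 8:
        import warnings

        warnings.warn(
            "fewer than 8 samples per cycle at the fastest expected rate; "
            "per-cycle extrema will be coarsely sampled",
            stacklevel=2,
        )
    return peaks


def _per_cycle_table(values: np.ndarray, peaks: np.ndarray) -> pd.DataFrame:
    rows = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = values[p0:p1]
        sys_, dia, mean = float(seg.max()), float(seg.min()), float(seg.mean())
        rows.append(
            {
                "systolic": sys_,
                "diastolic": dia,
                "mean": mean,
                "pi": (sys_ - dia) / mean if mean > 0 else np.nan,
                "ri": (sys_ - dia) / sys_ if sys_ > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _ensemble_beat(values: np.ndarray, smoothed: np.ndarray, peaks: np.ndarray,
                   n_phase: int = 64) -> np.ndarray:
    refined = np.array([_parabolic_vertex(smoothed, p)[0] for p in peaks])
    beats = []
    grid = np.arange(values.size)
    for p0, p1 in zip(refined[:-1], refined[1:]):
        phase = np.linspace(p0, p1, n_phase, endpoint=False)
        beats.append(np.interp(phase, grid, values))
    return np.mean(beats, axis=0)


def flow_indices(
    waveform: FlowWaveform,
    cycles: np.ndarray | None = None,
    mode: str = "ensemble",
    hr_range_hz: tuple[float, float] = (3.0, 15.0),
) -> HemodynamicIndices:
    """PI and RI of a flow waveform.

    modes: ``ensemble`` (default) — extrema of the phase-aligned average
    beat, quadratic-refined; ``per_cycle`` — mean of raw per-cycle indices;
    ``global`` — whole-trace max/min/mean.
    """
    v = waveform.values
    if mode == "global":
        sys_, dia, mean = float(v.max()), float(v.min()), float(v.mean())
        if mean <= 0:
            raise ValueError("non-positive mean flow")
        return HemodynamicIndices(
            pi=(sys_ - dia) / mean, ri=(sys_ - dia) / sys_ if sys_ > 0 else np.nan,
            n_cycles=0, per_cycle=pd.DataFrame(), mode="global",
        )
    if cycles is None:
        cycles = detect_cycles(waveform, hr_range_hz)
    table = _per_cycle_table(v, cycles)
    if table.empty:
        raise ValueError("need at least one complete cycle")
    if mode == "per_cycle":
        if (table["mean"] <= 0).any():
            raise ValueError("non-positive mean flow in a cycle")
        return HemodynamicIndices(
            pi=float(table["pi"].mean()), ri=float(table["ri"].mean()),
            n_cycles=len(table), per_cycle=table,
            pi_sd=float(table["pi"].std(ddof=1)) if len(table) > 1 else float("nan"),
            ri_sd=float(table["ri"].std(ddof=1)) if len(table) > 1 else float("nan"),
            mode="per_cycle",
        )
    if mode != "ensemble":
        raise ValueError(f"unknown mode {mode!r}")
    hr_hi = hr_range_hz[1]
    window = max(3, int(round(waveform.fs_hz / hr_hi / 2)) | 1)
    beat = _ensemble_beat(v, _smooth(v, window), cycles)
    i_max, i_min = int(np.argmax(beat)), int(np.argmin(beat))
    _, sys_ = _parabolic_vertex(beat, i_max)
    _, dia = _parabolic_vertex(-beat, i_min)
    dia = -dia
    mean = float(beat.mean())
    if mean <= 0:
        raise ValueError("non-positive mean flow")
    if sys_ <= 0:
        raise ValueError("non-positive systolic flow")
    return HemodynamicIndices(
        pi=(sys_ - dia) / mean, ri=(sys_ - dia) / sys_,
        n_cycles=len(table), per_cycle=table,
        pi_sd=float(table["pi"].std(ddof=1)) if len(table) > 1 else float("nan"),
        ri_sd=float(table["ri"].std(ddof=1)) if len(table) > 1 else float("nan"),
        mode="ensemble",
    )


def pulsatility_index(waveform: FlowWaveform, cycles=None, mode: str = "ensemble") -> HemodynamicIndices:
    """(systolic - diastolic) / mean flow; see :func:`flow_indices`."""
    return flow_indices(waveform, cycles, mode)


def resistance_index(waveform: FlowWaveform, cycles=None, mode: str = "ensemble") -> HemodynamicIndices:
    """(systolic - diastolic) / systolic flow; see :func:`flow_indices`."""
    return flow_indices(waveform, cycles, mode)


def efflux_timecourse(times_min, vessel_roi_series, background_roi_series) -> EffluxSeries:
    """Background-corrected femoral-vein intensity curve (vessel - background)."""
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(vessel_roi_series, dtype=float)
    b = np.asarray(background_roi_series, dtype=float)
    if not (t.shape == v.shape == b.shape):
        raise ValueError("timestamp/series length mismatch")
    return EffluxSeries(times_min=t, vessel_intensity=v, background_intensity=b)


def roi_mean_from_image(image, center, diameter_mm: float, pixel_size_mm: float) -> float:
    """Mean intensity of pixels whose centers fall within a circular ROI.

    ``center`` is (row, col) in pixel coordinates.
    """
    img = np.asarray(image, dtype=float)
    r_pix = 0.5 * diameter_mm / pixel_size_mm
    cy, cx = center
    if (cy - r_pix < -0.5 or cx - r_pix < -0.5
            or cy + r_pix > img.shape[0] - 0.5 or cx + r_pix > img.shape[1] - 0.5):
        raise ValueError("ROI disc extends outside the image")
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_pix**2
    if not disc.any():
        raise ValueError("ROI contains no pixel centers; enlarge the diameter")
    return float(img[disc].mean())
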