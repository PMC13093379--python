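"""Gd-DOTA concentration from serial T1 maps, with reference-phantom
normalization.

Concentration follows from the fast-exchange linear relaxivity relation
``1/T1_post = 1/T1_pre + r1 * C`` (T1 in seconds, C in mM, r1 in
L mmol^-1 s^-1).  Each post-infusion timepoint is rescaled so that the
median concentration inside the 0.1 mM reference-phantom mask equals its
nominal value, which removes scanner gain drift across the 300-min
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "t1_to_concentration",
    "concentration_to_t1",
    "normalize_to_phantom",
    "roi_timecourse",
]

DEFAULT_R1 = 3.3  # L mmol^-1 s^-1; representative gadobutrol tissue relaxivity at 7 T


@dataclass
class ConcentrationSeries:
    """Per-voxel (or per-ROI) concentration vs time.

    ``conc_mM`` is indexed (grid..., timepoint); ``times_min`` starts at the
    pre-infusion baseline.
    """

    conc_mM: np.ndarray
    times_min: np.ndarray
    normalized: bool = False
    scale_factors: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.conc_mM.shape[-1] != self.times_min.size:
            raise ValueError("last axis of conc_mM must match times_min")
        if self.times_min.size >= 2 and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if self.normalized and self.scale_factors is not None and np.any(
            np.asarray(self.scale_factors) <= 0
        ):
            raise ValueError("scale factors must be positive")


def t1_to_concentration(t1_post_ms, t1_pre_ms, r1: float = DEFAULT_R1):
    """C [mM] = (1/T1_post - 1/T1_pre) / r1, with T1 in seconds.

    Negative values (T1 lengthening, typically noise) are retained; callers
    can inspect ``ConcentrationSeries.flags`` or clamp explicitly.
    """
    t1_post = np.asarray(t1_post_ms, dtype=float)
    t1_pre = np.asarray(t1_pre_ms, dtype=float)
    if np.any(t1_post <= 0) or np.any(t1_pre <= 0):
        raise ValueError("T1 values must be positive")
    if r1 <= 0:
        raise ValueError("relaxivity must be positive")
    return (1000.0 / t1_post - 1000.0 / t1_pre) / r1


def concentration_to_t1(conc_mM, t1_pre_ms, r1: float = DEFAULT_R1):
    """Inverse relation: 1/T1_post = 1/T1_pre + r1 * C (T1 in ms out)."""
    t1_pre = np.asarray(t1_pre_ms, dtype=float)
    if np.any(t1_pre <= 0) or r1 <= 0:
        raise ValueError("T1 and relaxivity must be positive")
    return 1000.0 / (1000.0 / t1_pre + r1 * np.asarray(conc_mM, dtype=float))


def normalize_to_phantom(
    series: ConcentrationSeries,
    phantom_mask: np.ndarray,
    nominal_mM: float = 0.1,
) -> ConcentrationSeries:
    """Rescale each timepoint so the phantom median equals ``nominal_mM``.

    The phantom statistic is the median over mask voxels (robust to edge
    voxels).  The baseline timepoint is left untouched (factor 1): baseline
    concentration is zero by construction, so there is nothing to scale
    against before infusion.
    """
    mask = np.asarray(phantom_mask, bool)
    if not np.any(mask):
        raise ValueError("empty phantom mask")
    conc = series.conc_mM.copy()
    n_t = series.times_min.size
    factors = np.ones(n_t)
    phantom_vals = conc[mask]  # (n_phantom, T)
    for t in range(1, n_t):
        med = float(np.nanmedian(phantom_vals[:, t]))
        if med <= 0:
            raise ValueError(f"phantom median <= 0 at timepoint index {t}")
        factors[t] = nominal_mM / med
    conc *= factors
    return ConcentrationSeries(
        conc_mM=conc,
        times_min=series.times_min,
        normalized=True,
        scale_factors=factors,
        flags=dict(series.flags),
    )


def roi_timecourse(series, region_mask: np.ndarray) -> np.ndarray:
    """Mean time-signal curve over a region (missing voxels excluded)."""
    conc = series.conc_mM if isinstance(series, ConcentrationSeries) else np.asarray(series, float)
    mask = np.asarray(region_mask, bool)
    if not np.any(mask):
        raise ValueError("empty region mask")
    return np.nanmean(conc[mask], axis=0)
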