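"""Synthetic digital phantom and signal generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* a 3-D digital phantom with tissue regions (T1, S0, kinetic rate
  constants), a CSF region that carries the tracer input function, and a
  0.1 mM reference-phantom box, imaged as a multi-flip-angle SPGR series
  over the post-infusion timepoints;
* double-angle long-TR image pairs for B1 mapping;
* pulsatile flow waveforms with designed pulsatility/resistance indices;
* vessel-centered 3-channel line profiles with a designed AQP4
  polarization index;
* sigmoidal femoral-vein efflux series with a background ROI.

The tracer input function is a gamma-variate emulating cisterna-magna
infusion (CSF-adjacent concentration peaking near 30 min).  All generators
are pure functions of their specs and seed; identical seeds give
bit-identical output.  Magnitude-MRI noise is Rician by default, waveform
and fluorescence noise Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aqp4 import LineProfile
from .hemodynamics import EffluxSeries, FlowWaveform
from .kinetics import InputFunction, KineticParams, euler_forward
from .t1map import SignalStack, spgr_signal

__all__ = [
    "AcquisitionSpec",
    "NoiseSpec",
    "Box",
    "TissueRegion",
    "PhantomSpec",
    "GroundTruth",
    "default_phantom",
    "impaired_phantom",
    "gamma_variate",
    "simulate_two_compartment",
    "generate_spgr_series",
    "generate_b1_pair",
    "generate_flow_waveform",
    "generate_vessel_profile",
    "generate_efflux_series",
    "generate_cohort_tscs",
    "DEFAULT_TIMEPOINTS_MIN",
]

DEFAULT_TIMEPOINTS_MIN = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0)


@dataclass(frozen=True)
class AcquisitionSpec:
    """VFA-SPGR and double-angle acquisition parameters."""

    flip_angles_deg: tuple = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    tr_ms: float = 16.0
    te_ms: float = 3.0
    timepoints_min: tuple = DEFAULT_TIMEPOINTS_MIN
    b1_angles_deg: tuple = (70.0, 140.0)
    b1_tr_ms: float = 10000.0
    relaxivity_r1: float = 3.3

    def __post_init__(self) -> None:
        fa = np.asarray(self.flip_angles_deg, float)
        if np.any(np.diff(fa) <= 0) or fa[0] <= 0 or fa[-1] > 90:
            raise ValueError("flip angles must be strictly increasing in (0, 90]")
        tp = np.asarray(self.timepoints_min, float)
        if tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must start at baseline 0 and increase")
        a1, a2 = self.b1_angles_deg
        if not np.isclose(a2, 2 * a1):
            raise ValueError("second B1 angle must be twice the first")
        if self.relaxivity_r1 <= 0 or self.tr_ms <= 0:
            raise ValueError("TR and relaxivity must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: 'none', 'gaussian' or 'rician'; snr = peak signal / sigma."""

    model: str = "none"
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.model != "none" and self.snr <= 0:
            raise ValueError("snr must be positive")

    def apply(self, signal: np.ndarray, rng: np.random.Generator,
              reference_peak: float | None = None) -> np.ndarray:
        """Add noise with sigma = reference_peak / snr (default: signal max).

        Passing the baseline-frame peak keeps sigma stationary across a
        dynamic series, as scanner noise is.
        """
        if self.model == "none":
            return signal
        sigma = float(reference_peak if reference_peak is not None else np.max(signal)) / self.snr
        if self.model == "gaussian":
            return np.maximum(signal + rng.normal(0, sigma, signal.shape), 0.0)
        re = signal + rng.normal(0, sigma, signal.shape)
        im = rng.normal(0, sigma, signal.shape)
        return np.sqrt(re**2 + im**2)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in fractional grid coordinates [0, 1]^3."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, bool)
        sl = tuple(
            slice(int(round(lo * n)), max(int(round(hi * n)), int(round(lo * n)) + 1))
            for (lo, hi), n in zip((self.x, self.y, self.z), grid_shape)
        )
        m[sl] = True
        return m


@dataclass(frozen=True)
class TissueRegion:
    label: str
    box: Box
    t1_pre_ms: float
    s0: float
    params: KineticParams | None = None  # None => region carries the input function

    def __post_init__(self) -> None:
        if self.t1_pre_ms <= 0 or self.s0 <= 0:
            raise ValueError(f"region {self.label!r}: T1 and S0 must be positive")


@dataclass(frozen=True)
class InputFunctionSpec:
    """Gamma-variate input: amplitude (mM), onset (min), shape, scale (min)."""

    amplitude_mM: float = 0.5
    onset_min: float = 0.0
    shape: float = 3.0
    scale_min: float = 10.0  # peak at onset + shape*scale = 30 min


def gamma_variate(t, spec: InputFunctionSpec = InputFunctionSpec()):
    """Gamma-variate curve normalized to peak at ``amplitude_mM``."""
    tt = np.maximum(np.asarray(t, float) - spec.onset_min, 0.0) / spec.scale_min
    with np.errstate(invalid="ignore"):
        y = (tt / spec.shape) ** spec.shape * np.exp(spec.shape - tt)
    return spec.amplitude_mM * np.where(tt > 0, np.nan_to_num(y), 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom geometry, tissue properties and kinetics."""

    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 0.18
    tissue_regions: tuple = ()
    phantom_box: Box = Box((0.02, 0.18), (0.02, 0.18), (0.02, 0.18))
    phantom_t1_ms: float = 2800.0
    phantom_s0: float = 900.0
    phantom_conc_mM: float = 0.1
    input_function: InputFunctionSpec = InputFunctionSpec()

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if not self.tissue_regions:
            raise ValueError("empty region list")
        cover = self.phantom_box.mask(self.grid_shape).astype(int)
        for r in self.tissue_regions:
            cover += r.box.mask(self.grid_shape)
        if cover.max() > 1:
            raise ValueError("tissue regions and phantom box must be disjoint")

    def region_masks(self) -> dict:
        return {r.label: r.box.mask(self.grid_shape) for r in self.tissue_regions}

    def phantom_mask(self) -> np.ndarray:
        return self.phantom_box.mask(self.grid_shape)


def default_phantom(grid_shape=(24, 24, 24)) -> PhantomSpec:
    """Desk-scale phantom: CSF slab (input), cortex and hippocampus boxes,
    0.1 mM reference box.  The full-acquisition geometry (100^3, 0.18 mm)
    is obtained by passing ``grid_shape=(100, 100, 100)``."""
    regions = (
        TissueRegion("csf", Box((0.30, 0.70), (0.30, 0.70), (0.02, 0.14)),
                     t1_pre_ms=2500.0, s0=1200.0, params=None),
        TissueRegion("cortex", Box((0.20, 0.80), (0.20, 0.80), (0.55, 0.85)),
                     t1_pre_ms=1700.0, s0=1000.0,
                     params=KineticParams(0.08, 0.05, 0.02, 0.01)),
        TissueRegion("hippocampus", Box((0.30, 0.70), (0.30, 0.70), (0.25, 0.50)),
                     t1_pre_ms=1800.0, s0=1000.0,
                     params=KineticParams(0.05, 0.03, 0.02, 0.01)),
    )
    return PhantomSpec(grid_shape=grid_shape, tissue_regions=regions)


def impaired_phantom(grid_shape=(24, 24, 24)) -> PhantomSpec:
    """Phantom emulating impaired glymphatic transport: influx (K1) and
    efflux (K2) halved relative to :func:`default_phantom`."""
    base = default_phantom(grid_shape)
    regions = tuple(
        r if r.params is None else replace(
            r, params=KineticParams(r.params.k1 / 2, r.params.k2 / 2, r.params.k3, r.params.k4)
        )
        for r in base.tissue_regions
    )
    return replace(base, tissue_regions=regions)


def simulate_two_compartment(
    params: KineticParams,
    input_curve: InputFunction,
    time_grid_min,
    step_min: float = 0.05,
):
    """Tissue/interstitial curves and their sum on ``time_grid_min``.

    Forward-Euler integration at ``step_min``, linearly interpolated onto
    the requested grid.
    """
    grid = np.asarray(time_grid_min, float)
    if grid.size >= 2 and step_min > np.min(np.diff(grid)):
        raise ValueError("step_min larger than the requested grid spacing")
    t, ct, ci = euler_forward(params, input_curve, float(grid[-1]), step_min)
    ct_g = np.interp(grid, t, ct)
    ci_g = np.interp(grid, t, ci)
    return ct_g, ci_g, ct_g + ci_g


@dataclass
class GroundTruth:
    """Everything the estimators are supposed to recover."""

    times_min: np.ndarray
    t1_ms: np.ndarray          # (grid..., T)
    conc_mM: np.ndarray        # (grid..., T)
    kappa: np.ndarray          # (grid...)
    region_labels: np.ndarray  # int grid; -1 = background
    region_names: dict = field(default_factory=dict)
    region_params: dict = field(default_factory=dict)
    brain_mask: np.ndarray = None
    phantom_mask: np.ndarray = None
    input_function: InputFunction = None


def _true_concentration(phantom: PhantomSpec, times: np.ndarray, gt_step_min: float):
    """Per-region true concentration curves at the acquisition timepoints."""
    input_fn = InputFunction(
        np.arange(0.0, times[-1] + 1.0, 1.0),
        gamma_variate(np.arange(0.0, times[-1] + 1.0, 1.0), phantom.input_function),
        source="csf_roi",
    )
    curves = {}
    for region in phantom.tissue_regions:
        if region.params is None:
            curves[region.label] = input_fn(times)
        else:
            _, _, total = simulate_two_compartment(region.params, input_fn, times, gt_step_min)
            curves[region.label] = total
    return curves, input_fn


def generate_spgr_series(
    phantom: PhantomSpec,
    acq: AcquisitionSpec = AcquisitionSpec(),
    noise: NoiseSpec = NoiseSpec(),
    kappa_map: np.ndarray | None = None,
    gt_step_min: float = 0.05,
):
    """Dynamic multi-flip-angle SPGR stack plus its ground truth.

    Returns ``(SignalStack, GroundTruth)`` with stack data indexed
    (grid..., timepoint, flip angle).  Tracer concentration shortens T1 via
    the relaxivity relation; the reference box is held at the nominal
    phantom concentration at every post-infusion timepoint (zero at
    baseline).
    """
    if np.asarray(acq.flip_angles_deg).max() >= 180:
        raise ValueError("flip angle >= 180 degrees")
    times = np.asarray(acq.timepoints_min, float)
    shape = tuple(phantom.grid_shape)
    n_t, n_a = times.size, len(acq.flip_angles_deg)

    curves, input_fn = _true_concentration(phantom, times, gt_step_min)
    conc = np.zeros(shape + (n_t,))
    t1_pre = np.zeros(shape)
    s0 = np.zeros(shape)
    labels = np.full(shape, -1, int)
    names, params = {}, {}
    for i, region in enumerate(phantom.tissue_regions):
        m = region.box.mask(shape)
        conc[m] = curves[region.label]
        t1_pre[m], s0[m] = region.t1_pre_ms, region.s0
        labels[m] = i
        names[i] = region.label
        params[region.label] = region.params
    pm = phantom.phantom_mask()
    phantom_curve = np.full(n_t, phantom.phantom_conc_mM)
    phantom_curve[0] = 0.0
    conc[pm] = phantom_curve
    t1_pre[pm], s0[pm] = phantom.phantom_t1_ms, phantom.phantom_s0

    brain = labels >= 0
    support = brain | pm
    t1_pre_safe = np.where(support, t1_pre, 1e9)
    r1 = acq.relaxivity_r1
    t1_t = 1000.0 / (1000.0 / t1_pre_safe[..., None] + r1 * conc)  # ms
    kappa = np.ones(shape) if kappa_map is None else np.asarray(kappa_map, float)

    alphas = np.asarray(acq.flip_angles_deg, float)
    signal = spgr_signal(
        s0[..., None, None],
        t1_t[..., :, None],
        alphas[None, :],
        acq.tr_ms,
        kappa[..., None, None],
    )
    signal[~support] = 0.0
    rng = np.random.default_rng(noise.seed)
    baseline_peak = float(signal[..., 0, :].max())
    signal = noise.apply(signal, rng, reference_peak=baseline_peak)
    stack = SignalStack(data=signal, acq=acq, mask=support, kind="vfa_dynamic")
    gt = GroundTruth(
        times_min=times,
        t1_ms=np.where(support[..., None], t1_t, np.nan),
        conc_mM=np.where(support[..., None], conc, np.nan),
        kappa=kappa,
        region_labels=labels,
        region_names=names,
        region_params=params,
        brain_mask=brain,
        phantom_mask=pm,
        input_function=input_fn,
    )
    return stack, gt


def generate_b1_pair(
    phantom: PhantomSpec,
    acq: AcquisitionSpec = AcquisitionSpec(),
    noise: NoiseSpec = NoiseSpec(),
    kappa_map: np.ndarray | None = None,
):
    """Long-TR double-angle image pair at nominal angles (alpha, 2 alpha).

    In the long-TR limit the signal is S0 sin(kappa * alpha), so the
    noiseless ratio S(2a)/S(a) equals 2 cos(kappa * a).
    """
    shape = tuple(phantom.grid_shape)
    kappa = np.ones(shape) if kappa_map is None else np.asarray(kappa_map, float)
    a1 = acq.b1_angles_deg[0]
    if np.any(kappa <= 0) or np.any(kappa * 2 * a1 > 180.0):
        raise ValueError("kappa map must satisfy 0 < kappa and kappa*2a <= 180 deg")
    s0 = np.zeros(shape)
    for region in phantom.tissue_regions:
        s0[region.box.mask(shape)] = region.s0
    s0[phantom.phantom_mask()] = phantom.phantom_s0
    img1 = s0 * np.sin(np.deg2rad(kappa * a1))
    img2 = s0 * np.sin(np.deg2rad(kappa * 2 * a1))
    rng = np.random.default_rng(noise.seed)
    return noise.apply(img1, rng), noise.apply(img2, rng)


def generate_flow_waveform(
    rate_hz: float = 7.0,
    systolic: float = 1.2,
    diastolic: float = 0.8,
    duration_s: float = 20.0,
    fs_hz: float = 120.0,
    noise: NoiseSpec = NoiseSpec(),
):
    """Raised-cosine pulsatile flow waveform with recorded ground truth.

    The noiseless cycle has max = systolic, min = diastolic and mean
    (systolic + diastolic)/2, so the designed indices are
    PI = (s - d)/mean and RI = (s - d)/s.
    """
    if not systolic >= diastolic > 0:
        raise ValueError("need systolic >= diastolic > 0")
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if fs_hz <= 2 * rate_hz:
        raise ValueError("sampling rate must exceed twice the pulse rate")
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    values = diastolic + (systolic - diastolic) * 0.5 * (1 - np.cos(2 * np.pi * rate_hz * t))
    rng = np.random.default_rng(noise.seed)
    if noise.model == "gaussian":
        values = values + rng.normal(0, systolic / noise.snr, values.shape)
    elif noise.model == "rician":
        values = noise.apply(values, rng)
    mean = 0.5 * (systolic + diastolic)
    truth = {
        "systolic": systolic,
        "diastolic": diastolic,
        "mean": mean,
        "pi": (systolic - diastolic) / mean,
        "ri": (systolic - diastolic) / systolic,
        "rate_hz": rate_hz,
    }
    return FlowWaveform(values=values, fs_hz=fs_hz), truth


def generate_vessel_profile(
    length_um: float = 50.0,
    vessel_width_um: float = 7.0,
    peri_intensity: float = 200.0,
    extra_intensity: float = 100.0,
    band_width_um: float = 1.5,
    spacing_um: float = 0.1,
    noise: NoiseSpec = NoiseSpec(),
):
    """Vessel-centered 3-channel line profile with a designed AQP4 index.

    CD31 is a Gaussian lumen profile with FWHM = vessel width; GFAP marks
    the astrocytic endfeet as two flanking Gaussians whose outer half-max
    sits exactly at the perivascular boundary (vessel radius +
    ``band_width_um``); AQP4 is ``peri_intensity`` inside that boundary and
    ``extra_intensity`` outside.  The designed polarization index is
    peri/extra.
    """
    if extra_intensity <= 0:
        raise ValueError("extra_intensity must be positive: index undefined otherwise")
    if peri_intensity < 0:
        raise ValueError("intensities must be non-negative")
    peri_edge = vessel_width_um / 2.0 + band_width_um
    if peri_edge >= length_um / 2.0:
        raise ValueError("perivascular band exceeds the profile half-length")
    x = np.arange(-length_um / 2.0, length_um / 2.0 + spacing_um / 2, spacing_um)
    fwhm_factor = np.sqrt(2 * np.log(2))
    sigma_c = vessel_width_um / (2 * fwhm_factor)
    cd31 = np.exp(-(x**2) / (2 * sigma_c**2))
    sigma_g = max(band_width_um / 2.0, 0.5)
    center_g = peri_edge - sigma_g * fwhm_factor
    gfap = np.exp(-((np.abs(x) - center_g) ** 2) / (2 * sigma_g**2))
    aqp4 = np.where(np.abs(x) <= peri_edge, peri_intensity, extra_intensity)

    rng = np.random.default_rng(noise.seed)
    if noise.model != "none":
        sigma = peri_intensity / noise.snr
        aqp4 = np.maximum(aqp4 + rng.normal(0, sigma, x.shape), 0.0)
        cd31 = np.maximum(cd31 + rng.normal(0, 1.0 / noise.snr, x.shape), 0.0)
        gfap = np.maximum(gfap + rng.normal(0, 1.0 / noise.snr, x.shape), 0.0)
    profile = LineProfile(
        positions_um=x,
        channels={"aqp4": aqp4, "cd31": 255.0 * cd31, "gfap": 255.0 * gfap},
    )
    truth = {
        "index": peri_intensity / extra_intensity,
        "peri_edge_um": peri_edge,
        "vessel_width_um": vessel_width_um,
    }
    return profile, truth


def generate_efflux_series(
    plateau: float,
    rate_per_min: float = 0.06,
    sample_every_min: float = 15.0,
    duration_min: float = 180.0,
    t_mid_min: float = 90.0,
    background_level: float = 20.0,
    noise: NoiseSpec = NoiseSpec(),
):
    """Sigmoidal femoral-vein efflux series with a constant background ROI.

    The background-corrected noiseless series equals the designed logistic
    ``plateau / (1 + exp(-rate (t - t_mid)))`` sampled every 15 min.
    """
    if plateau < 0:
        raise ValueError("plateau must be non-negative")
    if duration_min <= 0 or sample_every_min <= 0:
        raise ValueError("duration and sampling interval must be positive")
    t = np.arange(0.0, duration_min + sample_every_min / 2, sample_every_min)
    sigmoid = plateau / (1.0 + np.exp(-rate_per_min * (t - t_mid_min)))
    vessel = sigmoid + background_level
    background = np.full_like(t, background_level)
    rng = np.random.default_rng(noise.seed)
    if noise.model != "none":
        sigma = max(plateau, background_level) / noise.snr
        vessel = vessel + rng.normal(0, sigma, t.shape)
        background = background + rng.normal(0, sigma, t.shape)
    series = EffluxSeries(times_min=t, vessel_intensity=vessel, background_intensity=background)
    return series, {"designed_curve": sigmoid, "times_min": t}


def generate_cohort_tscs(
    params: KineticParams,
    n_subjects: int = 10,
    times_min=DEFAULT_TIMEPOINTS_MIN,
    input_spec: InputFunctionSpec = InputFunctionSpec(),
    jitter_frac: float = 0.08,
    noise_frac: float = 0.01,
    seed: int = 0,
    gt_step_min: float = 0.05,
):
    """Per-subject regional tracer curves around cohort-level kinetics.

    Each subject's rate constants are the cohort values perturbed by
    lognormal jitter (``jitter_frac`` coefficient of variation); curves get
    additive Gaussian noise of ``noise_frac`` times their peak, floored at
    zero.  Returns ``(curves (n, T), subject_params, times)``.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times_min, float)
    fine_t = np.arange(0.0, times[-1] + 1.0, 1.0)
    input_fn = InputFunction(fine_t, gamma_variate(fine_t, input_spec))
    curves, subjects = [], []
    for _ in range(n_subjects):
        jitter = rng.lognormal(mean=0.0, sigma=jitter_frac, size=4)
        k = KineticParams.from_array(params.as_array() * jitter)
        _, _, total = simulate_two_compartment(k, input_fn, times, gt_step_min)
        if noise_frac > 0:
            total = np.maximum(total + rng.normal(0, noise_frac * total.max(), total.shape), 0.0)
        curves.append(total)
        subjects.append(k)
    return np.array(curves), subjects, times
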