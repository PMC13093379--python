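"""B1 (flip-angle scale) mapping and variable-flip-angle SPGR T1 fitting.

The spoiled gradient-recalled echo (SPGR) steady-state signal is

    S(alpha) = S0 * sin(kappa*alpha) * (1 - E1) / (1 - E1*cos(kappa*alpha)),
    E1 = exp(-TR / T1),

where ``kappa`` is the ratio of actual to nominal flip angle.  ``kappa`` is
measured voxelwise by the double-angle method (DAM) from a long-TR pair at
nominal angles (alpha, 2*alpha); (S0, T1, kappa') are then estimated per
voxel by three-parameter nonlinear least squares over the flip-angle
series, with kappa' confined to a band around the DAM value.  TE is carried
as metadata only (T2* decay is absorbed into S0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SignalStack",
    "B1Map",
    "T1Fit",
    "spgr_signal",
    "compute_b1_map",
    "despot1_fit",
    "fit_spgr_voxel",
    "fit_t1_volume",
]

DEFAULT_T1_BOUNDS_MS = (100.0, 6000.0)
DEFAULT_KAPPA_BAND = 0.2  # kappa' constrained to [0.8, 1.2] x DAM kappa


def spgr_signal(s0, t1_ms, alpha_deg, tr_ms, kappa=1.0):
    """Closed-form SPGR steady-state signal (vectorized over any argument)."""
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float) * kappa)
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return s0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclass
class SignalStack:
    """Voxel signal volumes with acquisition metadata.

    ``data`` is indexed (grid..., flip angle) for kind ``vfa``,
    (grid..., timepoint, flip angle) for ``vfa_dynamic`` and
    (grid..., 2) for ``b1pair``.
    """

    data: np.ndarray
    acq: "object"  # AcquisitionSpec; duck-typed to avoid an import cycle
    mask: np.ndarray | None = None
    kind: str = "vfa"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("signal data must be non-negative")
        if self.kind in ("vfa", "vfa_dynamic"):
            n_alpha = len(self.acq.flip_angles_deg)
            if self.data.shape[-1] != n_alpha:
                raise ValueError(
                    f"last axis ({self.data.shape[-1]}) must match the "
                    f"{n_alpha} flip angles"
                )


@dataclass
class B1Map:
    """Voxelwise actual/nominal flip-angle ratio."""

    kappa: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.kappa[self.valid] <= 0):
            raise ValueError("kappa must be positive where valid")


def compute_b1_map(img_alpha, img_2alpha, nominal_alpha_deg: float = 70.0,
                   signal_floor: float = 0.0) -> B1Map:
    """Double-angle method: kappa = arccos(S(2a) / (2 S(a))) / a.

    Assumes the long-TR regime (full T1 recovery between excitations).
    Voxels whose single-angle signal is at or below ``signal_floor`` are
    flagged invalid (kappa set to 1 there) rather than raising.
    """
    s1 = np.asarray(img_alpha, dtype=float)
    s2 = np.asarray(img_2alpha, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"shape mismatch {s1.shape} vs {s2.shape}")
    if not 0 < nominal_alpha_deg < 90:
        raise ValueError("nominal flip angle must be in (0, 90) degrees")
    valid = s1 > signal_floor
    ratio = np.ones_like(s1)
    np.divide(s2, 2.0 * s1, out=ratio, where=valid)
    alpha = np.deg2rad(nominal_alpha_deg)
    kappa = np.arccos(np.clip(ratio, -1.0, 1.0)) / alpha
    kappa[~valid] = 1.0
    return B1Map(kappa=kappa, valid=valid)


def despot1_fit(signals, flip_angles_deg, tr_ms, kappa=1.0):
    """DESPOT1 linearization: regress S/sin(ka) on S/tan(ka); slope = E1.

    Returns ``(t1_ms, s0)``.  Exact on noiseless data with known kappa;
    used as the analytic initialization (and as an independent oracle in
    tests) for the nonlinear fit.  Vectorized: ``signals`` may be
    (..., n_alpha); kappa broadcasts over the leading axes.
    """
    s = np.asarray(signals, dtype=float)
    a = np.deg2rad(np.asarray(flip_angles_deg, dtype=float)) * np.asarray(kappa)[..., None] \
        if np.ndim(kappa) else np.deg2rad(np.asarray(flip_angles_deg, dtype=float)) * kappa
    y = s / np.sin(a)
    x = s / np.tan(a)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=-1)
    sxy = np.sum((x - xm) * (y - ym), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym[..., 0] - e1 * xm[..., 0]
        e1c = np.clip(e1, 1e-12, 1.0 - 1e-12)
        t1 = -tr_ms / np.log(e1c)
        s0 = intercept / (1.0 - e1c)
    return t1, s0


@dataclass
class T1Fit:
    t1_ms: float
    s0: float
    kappa_fit: float
    rss: float
    converged: bool
    n_starts: int = 1


def _spgr_residual(theta, signals, alphas_deg, tr_ms):
    s0, t1, kappa = theta
    return spgr_signal(s0, t1, alphas_deg, tr_ms, kappa) - signals


def fit_spgr_voxel(
    signals,
    flip_angles_deg,
    tr_ms: float,
    kappa: float = 1.0,
    *,
    t1_bounds_ms: tuple[float, float] = DEFAULT_T1_BOUNDS_MS,
    kappa_band: float = DEFAULT_KAPPA_BAND,
    n_starts: int = 5,
) -> T1Fit:
    """Three-parameter (S0, T1, kappa') SPGR fit for a single voxel.

    Multi-start: ``n_starts`` T1 initializations log-spaced over the bounds
    (plus the DESPOT1 analytic start), each solved by bounded least squares
    with kappa' restricted to ``(1 +/- kappa_band) * kappa``; the lowest
    residual sum of squares wins, ties broken by lower T1.
    """
    s = np.asarray(signals, dtype=float)
    alphas = np.asarray(flip_angles_deg, dtype=float)
    if s.shape != alphas.shape or s.size < 3:
        raise ValueError("need >= 3 flip angles with matching signals")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    lo, hi = t1_bounds_ms
    if not 0 < lo < hi:
        raise ValueError("inverted or non-positive T1 bounds")
    if not np.any(s > 0):
        return T1Fit(np.nan, np.nan, kappa, np.nan, converged=False, n_starts=0)

    # S0 upper bound: 10x the S0 implied by the weakest plausible signal
    # amplitude per unit S0 (longest T1 in bounds), not 10x the raw signal --
    # at TR << T1 the SPGR signal is only a few percent of S0.
    min_amp = max(spgr_signal(1.0, hi, alphas, tr_ms, kappa).max(), 1e-9)
    s0_hi = 10.0 * s.max() / min_amp
    k_lo, k_hi = (1.0 - kappa_band) * kappa, (1.0 + kappa_band) * kappa
    lower = np.array([1e-12, lo, k_lo])
    upper = np.array([s0_hi, hi, k_hi])

    t1_starts = list(np.geomspace(lo * 1.05, hi * 0.95, n_starts))
    t1_d, s0_d = despot1_fit(s, alphas, tr_ms, kappa)
    if np.isfinite(t1_d) and lo < t1_d < hi:
        t1_starts.append(float(t1_d))
    best = None
    for t1_0 in t1_starts:
        s0_0 = s0_d if (np.isfinite(s0_d) and 0 < s0_d < s0_hi) else s.max() / max(
            spgr_signal(1.0, t1_0, alphas, tr_ms, kappa).max(), 1e-9
        )
        x0 = np.clip([s0_0, t1_0, kappa], lower + 1e-12, upper - 1e-12)
        res = least_squares(
            _spgr_residual, x0, args=(s, alphas, tr_ms), bounds=(lower, upper)
        )
        if (
            best is None
            or res.cost < best.cost - 1e-15
            or (abs(res.cost - best.cost) <= 1e-15 and res.x[1] < best.x[1])
        ):
            best = res
    s0_f, t1_f, k_f = best.x
    at_bound = t1_f <= lo * (1 + 1e-6) or t1_f >= hi * (1 - 1e-6)
    return T1Fit(
        t1_ms=float(t1_f),
        s0=float(s0_f),
        kappa_fit=float(k_f),
        rss=float(2 * best.cost),
        converged=bool(best.status > 0 and not at_bound),
        n_starts=len(t1_starts),
    )


@dataclass
class T1VolumeFit:
    """Voxelwise T1 map with diagnostics; NaN outside the mask."""

    t1_ms: np.ndarray
    s0: np.ndarray
    kappa: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    b1_invalid: np.ndarray = field(default=None)


def _gn_refine(s, alphas, tr_ms, s0, t1, kap, lower, upper, n_iter=40,
               kappa_prior=None, kappa_prior_weight=0.0):
    """Vectorized damped Gauss-Newton on (S0, T1, kappa') across voxels.

    An optional Gaussian prior pulls kappa' toward the measured DAM value
    with weight 1/sigma_kappa (in residual units), reflecting that the B1
    map is itself a measurement of finite precision.
    """
    a_nom = np.deg2rad(alphas)  # (A,)
    theta = np.stack([s0, t1, kap], axis=-1)  # (N, 3)
    theta = np.clip(theta, lower, upper)
    lam = np.full(theta.shape[0], 1e-3)
    if kappa_prior is None:
        kappa_prior = kap
    w2 = float(kappa_prior_weight) ** 2

    def model_and_jac(th):
        s0_, t1_, k_ = th[:, 0:1], th[:, 1:2], th[:, 2:3]
        a = a_nom[None, :] * k_
        u, c = np.sin(a), np.cos(a)
        e = np.exp(-tr_ms / t1_)
        denom = 1.0 - e * c
        m = s0_ * u * (1.0 - e) / denom
        d_s0 = u * (1.0 - e) / denom
        d_e = s0_ * u * (c - 1.0) / denom**2
        d_t1 = d_e * e * tr_ms / t1_**2
        d_k = s0_ * (1.0 - e) * a_nom[None, :] * (c * denom - e * u**2) / denom**2
        return m, np.stack([d_s0, d_t1, d_k], axis=-1)  # (N,A), (N,A,3)

    def full_cost(th, data_cost):
        return data_cost + w2 * (th[:, 2] - kappa_prior) ** 2

    model, jac = model_and_jac(theta)
    cost = full_cost(theta, np.sum((model - s) ** 2, axis=-1))
    for _ in range(n_iter):
        r = model - s  # (N, A)
        jtj = np.einsum("nai,naj->nij", jac, jac)
        jtr = np.einsum("nai,na->ni", jac, r)
        jtj[:, 2, 2] += w2
        jtr[:, 2] += w2 * (theta[:, 2] - kappa_prior)
        diag = np.einsum("nii->ni", jtj)
        # Levenberg damping: JtJ + lam * diag(JtJ)
        damped = jtj.copy()
        idx = np.arange(3)
        damped[:, idx, idx] += lam[:, None] * np.maximum(diag, 1e-12)
        try:
            delta = np.linalg.solve(damped, -jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            break
        trial = np.clip(theta + delta, lower, upper)
        m_t, j_t = model_and_jac(trial)
        cost_t = full_cost(trial, np.sum((m_t - s) ** 2, axis=-1))
        better = cost_t < cost
        theta[better] = trial[better]
        model[better], jac[better], cost[better] = m_t[better], j_t[better], cost_t[better]
        lam = np.where(better, lam * 0.3, lam * 4.0)
        lam = np.clip(lam, 1e-9, 1e6)
    return theta, cost


def fit_t1_volume(
    stack: SignalStack,
    b1map: B1Map | None = None,
    mask: np.ndarray | None = None,
    *,
    t1_bounds_ms: tuple[float, float] = DEFAULT_T1_BOUNDS_MS,
    kappa_band: float = DEFAULT_KAPPA_BAND,
    kappa_prior_sigma: float | None = 0.02,
) -> T1VolumeFit:
    """Fit T1/S0/kappa' for every masked voxel of a VFA stack.

    Vectorized across voxels: DESPOT1 analytic initialization followed by a
    damped Gauss-Newton refinement of the full three-parameter model (exact
    on noiseless data).  Because (S0, T1, kappa) are nearly degenerate in
    VFA data alone, kappa' carries a Gaussian prior centered on the
    measured DAM value with relative width ``kappa_prior_sigma`` (the B1
    map's own precision); set it to None for an unregularized fit.  Voxels
    with an invalid B1 estimate fall back to kappa = 1 and are flagged;
    masked-out voxels are NaN.
    """
    if stack.kind != "vfa":
        raise ValueError("fit_t1_volume expects a stack of kind 'vfa'")
    data = stack.data
    grid_shape = data.shape[:-1]
    if mask is None:
        mask = stack.mask if stack.mask is not None else np.ones(grid_shape, bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    alphas = np.asarray(stack.acq.flip_angles_deg, dtype=float)
    tr_ms = stack.acq.tr_ms

    if b1map is None:
        kappa = np.ones(grid_shape)
        b1_invalid = np.zeros(grid_shape, bool)
    else:
        kappa = np.where(b1map.valid, b1map.kappa, 1.0)
        b1_invalid = ~b1map.valid

    sig = data[mask]  # (N, A)
    kap = kappa[mask]
    t1_d, s0_d = despot1_fit(sig, alphas, tr_ms, kap)
    lo, hi = t1_bounds_ms
    t1_0 = np.where(np.isfinite(t1_d), np.clip(t1_d, lo * 1.01, hi * 0.99), 1500.0)
    min_amp = max(spgr_signal(1.0, hi, alphas, tr_ms).max(), 1e-9)
    s0_hi = 10.0 * max(sig.max(), 1.0) / min_amp
    s0_0 = np.where(
        np.isfinite(s0_d) & (s0_d > 0) & (s0_d < s0_hi), s0_d, sig.max(axis=-1) / min_amp
    )
    lower = np.stack(
        [np.full_like(kap, 1e-9), np.full_like(kap, lo), (1 - kappa_band) * kap], axis=-1
    )
    upper = np.stack(
        [np.full_like(kap, s0_hi), np.full_like(kap, hi), (1 + kappa_band) * kap], axis=-1
    )
    prior_w = 0.0 if kappa_prior_sigma is None else sig.max() / kappa_prior_sigma
    theta, cost = _gn_refine(
        sig, alphas, tr_ms, s0_0, t1_0, kap, lower, upper,
        kappa_prior=kap, kappa_prior_weight=prior_w,
    )

    def volume(values, fill=np.nan):
        out = np.full(grid_shape, fill, dtype=float)
        out[mask] = values
        return out

    t1_v = theta[:, 1]
    at_bound = (t1_v <= lo * (1 + 1e-6)) | (t1_v >= hi * (1 - 1e-6))
    conv = np.zeros(grid_shape, bool)
    conv[mask] = ~at_bound & np.all(np.isfinite(theta), axis=-1)
    return T1VolumeFit(
        t1_ms=volume(t1_v),
        s0=volume(theta[:, 0]),
        kappa=volume(theta[:, 2]),
        rss=volume(cost),
        converged=conv,
        b1_invalid=b1_invalid & np.asarray(mask, bool),
    )
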