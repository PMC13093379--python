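"""Two-compartment exchange model of parenchymal tracer kinetics.

The model describes exchange of a CSF-borne tracer between a local input
pool ``Cin`` (perivascular/CSF), a tissue compartment ``Ct`` and an
interstitial compartment ``Ci``::

    dCt/dt = K1*Cin(t) - (K2 + K3)*Ct + K4*Ci
    dCi/dt = K3*Ct - K4*Ci

with rate constants in 1/min: K1 influx, K2 efflux, K3/K4 the reversible
tissue<->interstitial exchange.  Integration is explicit forward Euler;
fitting is bounded weighted nonlinear least squares from dispersed
Latin-hypercube starts, with non-negativity enforced through the bounds.

The measured voxel (or cluster) concentration is by default the total
parenchymal tracer ``Ct + Ci``; ``observable="ct"`` restricts the
observation equation to the tissue compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "KineticParams",
    "InputFunction",
    "KineticFit",
    "FitDiagnostics",
    "euler_forward",
    "fit_kinetics",
    "assess_fit",
    "local_input_for_cluster",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-compartment exchange model, in 1/min."""

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"rate constants must be finite, got {arr}")
        if np.any(arr < 0):
            raise ValueError(f"rate constants must be non-negative, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "KineticParams":
        k1, k2, k3, k4 = np.asarray(arr, dtype=float)
        return cls(k1, k2, k3, k4)

    @property
    def k3_k4_ratio(self) -> float:
        """Exchange ratio K3/K4 (NaN when K4 = 0)."""
        return self.k3 / self.k4 if self.k4 > 0 else float("nan")


@dataclass(frozen=True)
class InputFunction:
    """Sampled local input concentration curve (mM vs minutes)."""

    times_min: np.ndarray
    conc_mM: np.ndarray
    source: str = "user"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.conc_mM, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times_min and conc_mM must be 1-D arrays of equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times_min must be strictly increasing with >= 2 samples")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "conc_mM", c)

    def __call__(self, t) -> np.ndarray:
        """Linearly interpolate the input concentration at time(s) ``t``."""
        return np.interp(t, self.times_min, self.conc_mM)


def euler_forward(
    params: KineticParams,
    input_function: InputFunction,
    t_end_min: float,
    step_min: float = 0.25,
    initial_state: tuple[float, float] = (0.0, 0.0),
    _max_halvings: int = 10,
):
    """Integrate the exchange ODEs by explicit forward Euler.

    Returns ``(t_grid, ct, ci)``.  If a non-negative input and parameters
    would still produce negative states (step beyond the stability limit
    ~1/(K2+K3+K4)), the step is halved automatically, up to
    ``_max_halvings`` times; the returned grid reflects the step used.
    """
    if step_min <= 0:
        raise ValueError("step_min must be positive")
    if input_function.times_min[-1] < t_end_min - 1e-9:
        raise ValueError(
            f"input function ends at {input_function.times_min[-1]} min, "
            f"before t_end {t_end_min} min"
        )
    nonneg_regime = (
        np.all(input_function.conc_mM >= 0)
        and initial_state[0] >= 0
        and initial_state[1] >= 0
    )
    k1, k2, k3, k4 = params.as_array()
    h = float(step_min)
    for _ in range(_max_halvings + 1):
        n = int(np.ceil(t_end_min / h - 1e-9))
        t_grid = np.linspace(0.0, n * h, n + 1)
        cin = input_function(t_grid)
        ct = np.empty(n + 1)
        ci = np.empty(n + 1)
        ct[0], ci[0] = initial_state
        for i in range(n):
            ct[i + 1] = ct[i] + h * (k1 * cin[i] - (k2 + k3) * ct[i] + k4 * ci[i])
            ci[i + 1] = ci[i] + h * (k3 * ct[i] - k4 * ci[i])
        if not nonneg_regime or (ct.min() >= -1e-12 and ci.min() >= -1e-12):
            return t_grid, ct, ci
        h /= 2.0
    raise RuntimeError("Euler step halving failed to restore non-negativity")


def _model_curve(theta, input_function, obs_times, step_min, observable):
    params = KineticParams.from_array(np.maximum(theta, 0.0))
    t_grid, ct, ci = euler_forward(params, input_function, obs_times[-1], step_min)
    y = ct + ci if observable == "sum" else ct
    return np.interp(obs_times, t_grid, y)


@dataclass
class KineticFit:
    params: KineticParams
    rss_weighted: float
    n_starts: int
    best_start_index: int
    converged: bool
    step_min: float
    residuals: np.ndarray
    observable: str = "sum"
    bounds: tuple[float, float] = (0.0, 1.0)
    model_curve: np.ndarray | None = None


def fit_kinetics(
    observed_tsc,
    input_function: InputFunction,
    *,
    obs_times_min=None,
    bounds: tuple[float, float] = (0.0, 1.0),
    n_starts: int = 20,
    weights=None,
    step_min: float = 0.25,
    seed: int = 0,
    observable: str = "sum",
) -> KineticFit:
    """Fit K1..K4 to an observed concentration curve.

    ``observed_tsc`` is either an array of concentrations sampled at
    ``obs_times_min`` or a ``(times, values)`` pair.  The weighted residual
    sum of squares ``sum w_t (obs_t - model_t)^2`` is minimised over the box
    ``[lb, ub]^4`` by a bounded trust-region least-squares solver started
    from ``n_starts`` Latin-hypercube points; the best start wins.
    Uniform weights by default; pass per-timepoint weights (1/sigma^2) for
    heteroscedastic noise.
    """
    if obs_times_min is None:
        obs_times_min, observed_tsc = observed_tsc
    obs_times = np.asarray(obs_times_min, dtype=float)
    obs = np.asarray(observed_tsc, dtype=float)
    if obs.shape != obs_times.shape:
        raise ValueError("observed curve and times must have matching shapes")
    if observable not in ("sum", "ct"):
        raise ValueError("observable must be 'sum' or 'ct'")
    if obs.size < 5:
        raise ValueError("need at least 5 observations to fit 4 rate constants")
    if weights is None:
        w = np.ones_like(obs)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with at least one positive")
    sqrt_w = np.sqrt(w)
    lb, ub = bounds
    if not 0 <= lb < ub:
        raise ValueError("bounds must satisfy 0 <= lb < ub")

    def objective(theta):
        return sqrt_w * (_model_curve(theta, input_function, obs_times, step_min, observable) - obs)

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = lb + sampler.random(n_starts) * (ub - lb)
    best = None
    best_idx = -1
    for i, start in enumerate(starts):
        res = least_squares(objective, start, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-15)
        if best is None or res.cost < best.cost - 1e-15:
            best, best_idx = res, i
    theta = best.x
    model = _model_curve(theta, input_function, obs_times, step_min, observable)
    return KineticFit(
        params=KineticParams.from_array(theta),
        rss_weighted=float(np.sum(w * (obs - model) ** 2)),
        n_starts=n_starts,
        best_start_index=best_idx,
        converged=bool(best.status > 0),
        step_min=step_min,
        residuals=obs - model,
        observable=observable,
        bounds=(lb, ub),
        model_curve=model,
    )


@dataclass
class FitDiagnostics:
    r_squared: float
    boundary_flags: dict = field(default_factory=dict)
    residual_mean: float = 0.0
    residual_std: float = 0.0
    residuals_normal: bool = True


def assess_fit(fit: KineticFit, observed, boundary_tol: float = 1e-3) -> FitDiagnostics:
    """Goodness-of-fit diagnostics: R^2, boundary proximity, residual summary."""
    obs = np.asarray(observed, dtype=float)
    if obs.shape != fit.residuals.shape:
        raise ValueError("observed curve length does not match the fit")
    ss_res = float(np.sum(fit.residuals**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    lb, ub = fit.bounds
    span = ub - lb
    flags = {}
    for name, val in zip(("k1", "k2", "k3", "k4"), fit.params.as_array()):
        at_lower = val - lb <= boundary_tol * span
        at_upper = ub - val <= boundary_tol * span
        flags[name] = "lower" if at_lower else ("upper" if at_upper else None)
    normal = True
    if fit.residuals.size >= 3 and np.ptp(fit.residuals) > 0:
        from scipy.stats import shapiro

        normal = bool(shapiro(fit.residuals).pvalue > 0.05)
    return FitDiagnostics(
        r_squared=r2,
        boundary_flags=flags,
        residual_mean=float(fit.residuals.mean()),
        residual_std=float(fit.residuals.std()),
        residuals_normal=normal,
    )


def local_input_for_cluster(
    tree,
    cluster_id: int,
    conc_matrix,
    times_min,
    strategy: str = "csf_roi",
    *,
    csf_member_ids=None,
    user_curve: InputFunction | None = None,
) -> InputFunction:
    """Construct the local input function for one cluster.

    strategies: ``csf_roi`` — mean curve over ``csf_member_ids`` (voxel rows
    of ``conc_matrix`` inside a CSF/perivascular mask); ``parent_cluster`` —
    representative curve of the cluster's parent node; ``user`` — an
    externally supplied curve returned unchanged.
    """
    times = np.asarray(times_min, dtype=float)
    if strategy == "user":
        if user_curve is None:
            raise ValueError("strategy 'user' requires user_curve")
        return user_curve
    if strategy == "csf_roi":
        if csf_member_ids is None or len(csf_member_ids) == 0:
            raise ValueError("strategy 'csf_roi' requires a non-empty csf_member_ids")
        curve = np.asarray(conc_matrix, dtype=float)[np.asarray(csf_member_ids)].mean(axis=0)
        return InputFunction(times, curve, source="csf_roi")
    if strategy == "parent_cluster":
        node = tree.nodes[cluster_id]
        if node.parent_id is None:
            raise ValueError("root cluster has no parent to serve as input")
        parent = tree.nodes[node.parent_id]
        curve = np.asarray(conc_matrix, dtype=float)[parent.member_ids].mean(axis=0)
        return InputFunction(times, curve, source="parent_cluster")
    raise ValueError(f"unknown input-function strategy {strategy!r}")
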