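# Methods

This note records the models implemented, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices that
shape the results.

## Acquisition model and T1 estimation

The VFA-SPGR stage assumes ideal spoiling and a mono-exponential T1: the
steady-state signal is S0·sin(κα)(1−E1)/(1−E1·cos(κα)) with
E1 = exp(−TR/T1). TE is carried as metadata only; T2*-weighting is a
constant factor at fixed TE and is absorbed into S0. Defaults follow the
acquisition the package targets: six flip angles (2°, 5°, 10°, 15°, 20°,
30°), TR 16 ms, TE 3 ms, and dynamic timepoints at 0 (baseline) and
30–300 min post-infusion.

B1 mapping uses the double-angle identity κ = arccos(S2α/2Sα)/α under the
long-TR assumption (TR 10 s); no refocusing-chain correction is applied.
Voxels with single-angle signal at or below a configurable floor are
flagged invalid and fall back to κ = 1 in the T1 fit.

T1 fitting is the three-parameter (S0, T1, κ′) nonlinear least-squares fit
of the SPGR model, κ′ hard-bounded within ±20% of the measured double-angle
κ. Two facts shaped the implementation:

* (S0, T1, κ) are nearly degenerate in VFA data alone — a classic
  identifiability limit. A genuinely free κ′, even inside the ±20% box,
  inflates T1 errors to tens of percent at realistic noise. The volume
  fitter therefore treats the measured κ as data: a Gaussian prior pulls κ′
  toward the double-angle value with relative width `kappa_prior_sigma`
  (default 0.02, the typical precision of a long-TR double-angle map). Set
  it to `None` for the unregularized fit.
* The S0 upper bound is scaled by the smallest normalized signal amplitude
  the model can produce within the T1 bounds. A bound proportional to the
  raw signal maximum would clip the true S0 whenever TR ≪ T1 (the SPGR
  signal is only a few percent of S0 at TR 16 ms).

`fit_t1_volume` is fully vectorized: a closed-form DESPOT1 regression
(S/sin(κα) on S/tan(κα); slope = E1) initializes a damped Gauss–Newton
refinement across all voxels. On noiseless data this is exact to solver
precision; the per-voxel `fit_spgr_voxel` (five log-spaced T1 multi-starts
plus the DESPOT1 start, ties broken by lower RSS then lower T1) is the
reference path and agrees with the vectorized one. T1 bounds default to
[100, 6000] ms; fits ending on a bound are flagged non-converged.
Masked-out voxels are NaN, never zero.

## Concentration and normalization

Concentration uses the fast-exchange linear relation
C = (1/T1_post − 1/T1_pre)/r1 with r1 = 3.3 L mmol⁻¹ s⁻¹ by default — a
representative tissue relaxivity for gadobutrol at 7 T, exposed in the
configuration rather than asserted as *the* value, since relaxivity varies
with field and tissue. Negative concentrations (noise-driven T1
lengthening) are retained and flagged rather than clamped, so weighting
schemes can see them; clamping is a caller decision.

Each post-infusion timepoint is rescaled so the median concentration inside
the reference-phantom mask equals 0.1 mM; the median is robust to phantom
edge voxels. The baseline timepoint keeps scale factor 1: concentration is
measured relative to the baseline T1 map, so the phantom reads zero before
infusion and there is nothing to normalize against. Normalizing an
already-normalized series with a perfect phantom is a no-op.

## Clustering

Features are finite-difference derivatives of each voxel's TSC,
(x_{j+1} − x_j)/(t_{j+1} − t_j), which makes the similarity measure respond
to kinetics rather than to static offsets. The stored feature matrix is
normalized by the global maximum |derivative| (a dimensionless [-1, 1]
scale; the constant is kept for invertibility).

The within-cluster inconsistency is defined as relative dispersion:

    WCI = mean_i ‖f_i − centroid‖ / ‖centroid‖.

This makes the 0.125 threshold meaningful across brain regions whose
enhancement differs by an order of magnitude: a cluster of one kinetic
family with measurement noise has WCI well below 0.125 (noise over signal
on the derivative scale), while a mixture of distinct families sits above
it, regardless of amplitude and of the sampling grid. An absolute
(non-relative) dispersion cannot do this: families with weak enhancement
would always fall below any fixed threshold and never separate. The
degenerate case of a zero centroid with disagreeing members is treated as
maximally inconsistent; clusters of identical members have WCI 0.

Splitting is 2-means (scikit-learn, k-means++ with 10 restarts), seeded
deterministically per node from the tree seed and node id, children ordered
by lexicographically smaller centroid. A cluster is split only while
count > 100 AND WCI > 0.125; an empty-child split makes the node a flagged
leaf, and `max_depth` (default 12) is a safety cap. Leaves partition the
voxel set by construction. Representative TSCs are means of the original
(not derivative) curves.

## Kinetic model and fitting

The two-compartment exchange system (influx K1, efflux K2, reversible
tissue↔interstitial exchange K3/K4, all min⁻¹, all ≥ 0) is integrated by
explicit forward Euler with the input linearly interpolated onto the
integration grid (default step 0.25 min; 0.1 min in the pipeline). If a
non-negative problem would produce negative states — the step beyond the
~1/(K2+K3+K4) stability limit — the step is halved automatically. Euler is
first order: against an adaptive Runge–Kutta (DOP853) reference the
max-abs deviation halves exactly with the step and is ~1e-3 mM at step
0.1 min for a 0.5 mM-peak input (the deviation scales as
(h/2)·K1·TV(Cin), i.e. linearly in both step and input amplitude).

The observation equation defaults to Ct + Ci — total parenchymal tracer,
the physically standard reading of a voxel concentration —
with `observable="ct"` available. This choice has a real statistical
consequence: with only the total observable, K2 and especially K3 are
weakly identifiable from 8 timepoints. A Cramér–Rao analysis at 5%
proportional noise puts the best achievable median relative errors near
8% (K1), 24% (K2), 28% (K3) and 8% (K4); the recovery simulations measure
medians matching those bounds, so the fitted exchange constants should be
read as order-of-magnitude under realistic noise unless curves are
averaged over many voxels (as the clustering stage does). Under the
Ct-only observable all four constants are identifiable to better than 10%.

Fitting minimizes Σ w_t (obs_t − model_t)² by bounded trust-region least
squares from Latin-hypercube starts over [0, 1] min⁻¹ (default 20 starts;
fewer suffice on noiseless curves), best weighted RSS wins. Weights default
to uniform; for heteroscedastic noise pass w = 1/σ² (the recovery
simulations use 5% proportional noise with matching weights — the setting
under which weighted least squares is the maximum-likelihood estimator).
Non-negativity is enforced by the bounds, never violated. Local input
functions come from a CSF ROI mean (default), the parent cluster's
representative curve, or a user curve.

## Model-free metrics

TTP is the time of the global maximum, ties broken earliest; a peak at the
final sample flags `no_decay`. The 90%/10%-of-peak crossing times are
located by linear interpolation between samples — on a 30-min grid the
crossings are otherwise unattainable — and when the curve has not decayed
to 10% of peak within the window, the terminal linear segment is
extrapolated to the crossing and `washout_extrapolated` is set (slowly
clearing subjects would otherwise have undefined washout). Retention at
300 min interpolates linearly if that exact time is missing, with a flag.
Baseline Gd_pre is the single pre-infusion sample by default. Retention is
affine-invariant; wash-in/washout scale linearly with amplitude and
wash-in is shift-invariant — these are tested properties.

## Hemodynamic indices

Cycles are detected by peak finding on a lightly smoothed trace (minimum
inter-peak distance fs/hr_max, prominence 0.3 of range); a warning is
emitted below 8 samples/cycle. The default index extraction is an
ensemble-averaged beat: each cycle is phase-aligned on sub-sample-refined
systolic peaks, resampled to a common phase grid, averaged across the
~140 beats of a 20-s trace, and the extrema of the averaged beat are
quadratically refined. The reason is statistical: raw per-cycle sample
extrema are order statistics whose noise bias (~2σ·E[max]) does not
average away across cycles and exceeds 20% of the pulse amplitude at
SNR 20 with ~17 samples/cycle; beat averaging reduces the noise by √n
before the extrema are taken. `per_cycle` (mean of raw per-cycle indices,
with SD, partial first/last cycles discarded) and `global` (whole-trace
max/min/mean) modes are available, and the per-cycle table — where
RI = PI·mean/systolic holds exactly — always accompanies the result.
End-diastolic flow is the minimum between successive systolic peaks.

## AQP4 polarization

The perivascular interval is the contiguous region around the CD31 peak
where the union of CD31 and GFAP, each normalized to its own maximum,
stays above half-max, with boundaries refined by linear interpolation. The
index is the mean AQP4 intensity inside the interval over the mean across
the two flanking 15-µm bands (clipped at profile ends; a fully clipped
side flags `one_sided_extra`, zero extraperivascular signal flags
`zero_extra` with NaN index). The index is invariant to global AQP4
scaling and profile reversal and strictly increasing in perivascular
signal — the operational meaning of "higher index = more polarized". The
vessel lumen is not excluded from the perivascular mean. 2-D images are
supported only through a profile-extraction helper at a user-supplied
vessel center.

## Synthetic data: what it emulates, what it does not

The digital phantom (default 24³ voxels, 0.18 mm isotropic; the full
acquisition geometry is 100³) contains a CSF slab that carries the tracer
input function, cortex and hippocampus boxes with two-compartment
kinetics (cortex K = 0.08, 0.05, 0.02, 0.01 min⁻¹; hippocampus 0.05,
0.03, 0.02, 0.01; an "impaired" variant halves K1 and K2), and a
reference box whose true concentration is 0.1 mM at every post-infusion
timepoint and 0 at baseline. The input function is a gamma-variate peaking
at 0.5 mM at 30 min — a stand-in for cisterna-magna infusion chosen for
timing and CSF-scale amplitude, not an inference about any real dataset.
MRI noise is Rician on magnitude signals with σ referenced to the
baseline-frame peak (scanner noise is stationary across a dynamic series);
waveform and fluorescence noise are Gaussian. Every generator is a pure
function of its specs and seed.

Not emulated: k-space sampling, motion, flow and partial-volume effects,
spoiling imperfections, B0 inhomogeneity, physiological variability of the
input function, vessel geometry beyond a straight profile. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to every artifact of in vivo data.

## Problem sizes and reproducibility

The shipped tests and the acceptance script run desk-scale problems: 24³
volumes, 600-voxel clustering sets, 100-replicate noise recoveries with 10
multi-starts at 0.5-min Euler steps, 20-s waveforms, 501-sample profiles.
The pipeline records a manifest (config hash, seed, package version,
per-stage SHA-256 checksums); identical config and seed reproduce
identical checksums, which the tests assert.

## Known limitations

* End-to-end kinetic recovery is limited by the 8-timepoint sampling of
  the input function (linear interpolation flattens its peak): expect
  ~10% bias on K1/K2 and up to ~20% on the weakly identifiable K3/K4 even
  on noiseless data.
* K2/K3 medians under 5% noise sit at their Cramér–Rao bounds (~20–26%)
  under the total-tracer observable; this is information, not
  implementation.
* Forward Euler at the default steps contributes ~0.1–1% model error
  relative to curve amplitude; halve the step to halve it.
* The double-angle B1 relation assumes ideal long-TR gradient-echo
  behavior; RARE-specific refocusing corrections are out of scope.
* No spatial regularization anywhere: clustering ignores voxel adjacency
  by design, and masks must share the acquisition grid (no resampling).
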