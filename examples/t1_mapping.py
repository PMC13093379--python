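"""Voxelwise B1 and T1 mapping on the synthetic phantom.

Estimates the flip-angle scale kappa by the double-angle method, then fits
the three-parameter SPGR model (S0, T1, kappa') per voxel, and compares
the result with the generator's ground truth.
"""

import numpy as np

from glymphkin import (
    AcquisitionSpec,
    SignalStack,
    compute_b1_map,
    default_phantom,
    fit_t1_volume,
    generate_b1_pair,
    generate_spgr_series,
)

phantom = default_phantom()
acq = AcquisitionSpec()
stack, truth = generate_spgr_series(phantom, acq)
img70, img140 = generate_b1_pair(phantom, acq)

b1 = compute_b1_map(img70, img140, nominal_alpha_deg=acq.b1_angles_deg[0])
print(f"B1 map: kappa = {np.nanmean(b1.kappa[b1.valid]):.4f} "
      f"(1.0 = nominal flip angle realized exactly)")

baseline = SignalStack(stack.data[..., 0, :], acq, mask=truth.brain_mask, kind="vfa")
fit = fit_t1_volume(baseline, b1map=b1, mask=truth.brain_mask)
err = np.abs(fit.t1_ms - truth.t1_ms[..., 0]) / truth.t1_ms[..., 0]
print(f"baseline T1 fit on {truth.brain_mask.sum()} voxels:")
print(f"  max relative error {np.nanmax(err[truth.brain_mask]):.2e} "
      "(noiseless data: recovery is exact to solver precision)")
for label, idx in (("cortex", 1), ("hippocampus", 2)):
    m = truth.region_labels == idx
    print(f"  {label}: fitted T1 {np.nanmean(fit.t1_ms[m]):7.1f} ms, "
          f"true {np.nanmean(truth.t1_ms[..., 0][m]):7.1f} ms")
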