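"""Generate the synthetic digital phantom and its dynamic SPGR acquisition.

Builds the default 24^3 phantom (CSF slab, cortex, hippocampus, 0.1 mM
reference box), images it at six flip angles over the eight acquisition
timepoints, and prints what the generator knows to be true.
"""

import numpy as np

from glymphkin import AcquisitionSpec, NoiseSpec, default_phantom, generate_spgr_series

phantom = default_phantom()
acq = AcquisitionSpec()
stack, truth = generate_spgr_series(phantom, acq, NoiseSpec(model="none"))

print(f"signal stack shape (x, y, z, timepoint, flip angle): {stack.data.shape}")
print(f"flip angles: {acq.flip_angles_deg} deg, TR {acq.tr_ms} ms")
print(f"timepoints: {acq.timepoints_min} min")
print(f"brain voxels: {truth.brain_mask.sum()}, reference-phantom voxels: "
      f"{truth.phantom_mask.sum()}")
for label, params in truth.region_params.items():
    if params is None:
        print(f"  {label}: carries the gamma-variate input function "
              f"(peak 0.5 mM at 30 min)")
    else:
        print(f"  {label}: K1-K4 = {params.as_array()} 1/min")

cortex = truth.region_labels == 1
peak_conc = np.nanmax(truth.conc_mM[cortex])
print(f"peak cortex concentration: {peak_conc:.3f} mM")
print("Each region's concentration curve follows the two-compartment exchange")
print("model driven by the CSF input; T1 shortens with concentration via r1.")
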