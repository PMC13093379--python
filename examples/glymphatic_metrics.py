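"""Model-free glymphatic metrics on healthy versus impaired cohorts.

Generates regional tracer curves for a healthy cohort and an impaired one
(influx K1 and efflux K2 halved), computes time-to-peak, wash-in, washout
and 300-min retention per subject, and prints the cohort means.
"""

import numpy as np

from glymphkin import KineticParams, generate_cohort_tscs
from glymphkin.metrics import curve_metrics

cohorts = {
    "healthy": KineticParams(0.08, 0.05, 0.02, 0.01),
    "impaired": KineticParams(0.04, 0.02, 0.02, 0.01),
}
for name, params in cohorts.items():
    curves, _, times = generate_cohort_tscs(params, n_subjects=8, seed=1 if name == "healthy" else 2)
    ms = [curve_metrics(times, c) for c in curves]
    print(f"{name} cohort (n=8):")
    print(f"  TTP           {np.mean([m.ttp_min for m in ms]):7.1f} min")
    print(f"  wash-in rate  {np.mean([m.wash_in_rate for m in ms]):7.4f} /min")
    print(f"  washout rate  {np.mean([m.wash_out_rate for m in ms]):7.4f} /min")
    print(f"  retention@300 {np.mean([m.retention_ratio_pct for m in ms]):7.1f} %")
print("Impaired transport shows slower wash-in, slower washout and more tracer")
print("retained at 300 min -- the signature of reduced glymphatic clearance.")
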