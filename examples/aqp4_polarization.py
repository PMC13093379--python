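"""AQP4 polarization index from vessel-centered line profiles.

Generates 50-um three-channel profiles across ~7-um vessels, delineates
the perivascular space from CD31/GFAP, and computes the ratio of
perivascular to extraperivascular AQP4 intensity.
"""

from glymphkin import NoiseSpec, batch_polarization, generate_vessel_profile

profiles = []
for width in (6.0, 6.5, 7.0, 7.5, 8.0):
    prof, _ = generate_vessel_profile(
        vessel_width_um=width, peri_intensity=200.0, extra_intensity=100.0,
        noise=NoiseSpec(model="gaussian", snr=30.0, seed=int(width * 10)),
    )
    profiles.append(prof)

table, summary = batch_polarization(profiles, extra_band_um=15.0)
print(table[["index", "peri_mean", "extra_mean", "peri_start_um", "peri_end_um"]]
      .round(3).to_string())
print(f"\ncohort: mean index {summary['mean']:.3f} +/- {summary['sd']:.3f} "
      f"(n={summary['n']}, designed 2.0)")
print("Index > 1 means AQP4 is concentrated at perivascular astrocytic endfeet;")
print("values near 1 indicate depolarized, uniformly distributed AQP4.")
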