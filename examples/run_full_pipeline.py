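"""End-to-end analysis on the synthetic phantom (~1 minute).

B1 mapping -> serial T1 mapping -> concentration + phantom normalization
-> hierarchical clustering -> per-cluster kinetic fitting -> regional
metrics, with a reproducibility manifest.
"""

from glymphkin import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, grid_shape=(24, 24, 24), noise_model="none",
                        kinetics_n_starts=6)
result = run_pipeline(config)

print("kinetic parameters per cluster (1/min):")
print(result.kinetic_table[["n_voxels", "k1", "k2", "k3", "k4"]].round(4).to_string())
print("\ntrue generator values: cortex (0.08, 0.05, 0.02, 0.01), "
      "hippocampus (0.05, 0.03, 0.02, 0.01)")

print("\nregional glymphatic metrics:")
cols = ["ttp_min", "wash_in_rate", "wash_out_rate", "retention_ratio_pct"]
print(result.metrics_table[cols].round(4).to_string())

print("\nstage checksums (identical config + seed reproduce these exactly):")
for stage, digest in result.manifest.checksums.items():
    print(f"  {stage:14s} {digest}")
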