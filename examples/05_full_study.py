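"""Run the whole pipeline on a synthetic study.

Generates a small study (paired surfaces across three light treatments,
overdispersed patterning, planted guard-cell lengths), then runs every
analysis stage: dispersion with family-wise BH adjustment, paired-surface
coordination, zone-area slopes, two-way ANOVAs, and a small FEM sweep.
"""

from amphistoma import pipeline

config = pipeline.RunConfig(out_dir="scratch/example_run", n_pairs=9,
                            n_sim=199, resolution=32, n_boot=200,
                            fem_grid_levels=2, seed=1)
tables = pipeline.run_all(config)

disp = tables["dispersion"]
print(f"surfaces analysed:       {len(disp)}")
print(f"median dispersion index: {disp['dispersion_index'].median():.3f}")
print(f"significantly overdispersed (BH-adjusted): "
      f"{(disp['p_adjusted'] <= 0.05).sum()} of {len(disp)}")
coordt = tables["coordination"]
print(f"pairs with significant coordination:       "
      f"{(coordt['p_adjusted'] <= 0.05).sum()} of {len(coordt)}")
print(f"max sweep advantage:     {tables['fem_sweep']['advantage'].max():.2e}")
print()
print("The fixture is overdispersed within each surface but uncoordinated")
print("between surfaces, which is exactly the pattern the analyses report;")
print("result tables were written to scratch/example_run/.")
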