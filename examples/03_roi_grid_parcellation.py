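"""Sample a synthetic calretinin-like field with the systematic ROI grid.

Builds the three-region intensity field (MDm | transition zone | core, with
core the brightest), tiles it with 89.51 um windows at 100 um spacing,
assigns each window a region by majority vote, and runs the gradient
analyses: one-way ANOVA with Tukey post hoc across regions and a line
profile crossing the region borders.
"""

import numpy as np

import axonquant as aq

image, label_map = aq.generate_region_field((300, 300), noise_sd=2.0, seed=9)

grid = aq.build_grid((300.0, 300.0), spacing_um=100, window_um=89.51, pixel_size_um=1.0)
aq.assign_regions(grid, label_map)
aq.measure_grid(grid, {"CR": image})

by_region: dict[str, list[float]] = {}
for w in grid.included:
    by_region.setdefault(w.region, []).append(w.measurements["mean_CR"])

print(f"{len(grid.included)} included windows")
for region in ("MDm", "transition", "core"):
    vals = by_region[region]
    print(f"  {region:<10} mean CR = {np.mean(vals):6.2f} AU  (n = {len(vals)} windows)")

aov = aq.anova_oneway(by_region)
print(f"one-way ANOVA: F({aov.df_num:.0f},{aov.df_den:.0f}) = {aov.F:.2f}, p = {aov.p:.2e}")
for _, row in aov.tukey.iterrows():
    print(f"  Tukey {row['group1']} vs {row['group2']}: "
          f"diff = {row['mean_diff']:+.2f} AU, adj. p = {row['p_adj']:.4f}")

profile = aq.line_profile(image, [(150.0, 10.0), (150.0, 290.0)],
                          band_width_um=20.0, step_um=5.0)
print(f"line profile: {profile.intensity[0]:.1f} AU at the MDm end -> "
      f"{profile.intensity[-1]:.1f} AU in the core")
print()
print("The grid recovers the imposed intensity gradient (core > transition")
print("> MDm) and the ANOVA confirms the region effect, mirroring how a CR")
print("fluorescence gradient delineates the thalamic core region.")
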