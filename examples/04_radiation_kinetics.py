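"""Biphasic repair kinetics for high- vs low-LET radiation presets.

Runs comparison-mode kinetics (irreparable sub-L_min fragments included) for
the Fe-ion preset (30% short, 10% irreparable) and the gamma-ray preset
(3% short, 1% irreparable) and prints the mean fraction of fragments
remaining, the quantity compared against repair-foci time courses.
"""

import numpy as np

from nhejsim import SimParams, mean_kinetics, preset

params = SimParams(include_irreparable=True)
grid = np.linspace(0.0, 60.0, 13)

print(f"{'time':>6}{'Fe ion P(t)':>13}{'gamma P(t)':>12}")
curves = {}
for name in ("fe_ion", "gamma"):
    dist = preset(name, m0=100, seed=4, include_irreparable=True)
    curves[name] = mean_kinetics(dist, params, 200, grid, 2001)

for i, t in enumerate(grid):
    print(f"{t:>6.0f}{curves['fe_ion'].p_mean[i]:>13.3f}"
          f"{curves['gamma'].p_mean[i]:>12.3f}")

print("\nBoth curves drop fast at first (long-fragment joins need no residue "
      "release), then crawl through the release-limited short-fragment phase. "
      "The Fe-ion curve plateaus at the irreparable fraction plus the final "
      "joined fragment; the gamma curve rejoins almost completely.")
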