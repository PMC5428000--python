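"""Free-energy barriers from umbrella sampling + WHAM.

Draws five harmonic umbrella windows (wells, transition state, midpoints;
~0.05 nm spacing, 8000 kcal/mol/nm^2 spring) from an analytic tilted
double well with known barriers, reconstructs the profile with WHAM over
several replicates, and reports barrier heights with error bars.
"""

import numpy as np

from poremsm import synthetic as syn, wham
from poremsm.wham import KT_300K

true_fwd, true_rev = 2.5, 2.0
well = syn.TiltedDoubleWell.from_barriers(true_fwd, true_rev)
centers = well.default_window_centers()
zl, zt, zr = well.stationary_points()
gap = 0.45 * (zt - zl)
span = centers.max() - centers.min()
grid = (centers.min() - 0.35 * span, centers.max() + 0.35 * span, 80)

profiles = []
for rep in range(8):
    windows = syn.gen_umbrella_samples(well, centers, 8000.0, 5000,
                                       kT=KT_300K, seed=10 + rep)
    profiles.append(wham.wham_solve(windows, kT=KT_300K, grid=grid,
                                    tol=1e-8))
overlap, ok = wham.histogram_overlap(windows, grid)
agg = wham.pmf_error_bars(profiles, well_windows=((zl - gap, zl + gap),
                                                  (zr - gap, zr + gap)))
b = agg["barriers"]

print(f"window centers (nm)  : {centers.round(3)}")
print(f"adjacent overlaps    : {overlap.round(4)} (flag {ok})")
print(f"forward barrier      : {b.forward:.2f} +/- {b.forward_sd:.2f} "
      f"kcal/mol (true {true_fwd})")
print(f"reverse barrier      : {b.reverse:.2f} +/- {b.reverse_sd:.2f} "
      f"kcal/mol (true {true_rev})")
print()
print("WHAM stitches the stiff, barely-overlapping windows into one")
print("profile; replicate spread gives honest error bars on the barriers.")
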