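"""From one ion to an action-potential's worth of calcium.

With unlimited sensor capacity, N simultaneously released ions act
independently: P_N = 1 - (1 - P)^N.  For temporally spread entry (about
200 ions over a 0.3 ms Gaussian time course during an action potential)
each trial multiplies the per-ion complements at the appropriate elapsed
times, and the trial average gives the expected occupancy P_AP(t).
"""

import numpy as np

import calsensor as cs

cfg = cs.default_config()
single = cs.occupancy_single(cfg, cs.default_time_grid())

print("Instantaneous release of N ions (at least one bound at the peak):")
for N in (1, 50, 200):
    pn = cs.occupancy_at_least_one(single, N)
    print(f"  N = {N:3d}: peak P_N = {np.max(pn.values):.3f}")

print()
print("At least n of N = 200 ions bound simultaneously (peak):")
for n in (1, 2, 5):
    pnn = cs.occupancy_at_least_n(single, 200, n)
    print(f"  n = {n}: peak = {np.max(pnn.values):.4f}")

print()
trials = [cs.gaussian_flux_fixture(200, fwhm=0.3, seed=100 + j) for j in range(200)]
p_ap = cs.occupancy_ap(trials, single)
print(f"Gaussian-spread influx (200 ions, 0.3 ms FWHM, 200 trials):")
print(f"  peak P_AP = {np.max(p_ap.values):.3f} "
      f"(lower than the instantaneous {np.max(cs.occupancy_at_least_one(single, 200).values):.3f}:")
print("  spreading the flux in time reduces the peak sensor occupancy)")
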