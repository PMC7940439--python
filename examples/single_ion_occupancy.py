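"""Occupancy of the vesicle-fusion sensor by a single Ca2+ ion.

A calcium ion enters the bouton 15 nm from the sensor surface and
diffuses; the occupancy probability P(t, r) rises to a peak of about
1% within tens of microseconds, then relaxes to a sub-1e-3 steady state
set by the binding/unbinding equilibrium over the bouton volume.
"""

import calsensor as cs

cfg = cs.default_config()  # R = 300 nm, rho = 5 nm, CD = 15 nm, no buffer
curve = cs.occupancy_single(cfg, cs.default_time_grid())
m = cs.curve_metrics(curve)

print(f"coupling distance : {cfg.geometry.cd:.0f} nm")
print(f"peak occupancy    : {m.peak:.4f}  (probability the ion is bound)")
print(f"time to peak      : {m.time_to_peak_us:.1f} us")
print(f"FWHM              : {m.fwhm_us:.1f} us")
print(f"steady state      : {m.steady_state:.2e} (closed form)")
print()
print("Shorter coupling distances give larger, earlier peaks:")
for cd in (5.0, 45.0, 95.0):
    c = cfg.with_geometry(r=cfg.geometry.rho + cd)
    mm = cs.curve_metrics(cs.occupancy_single(c, cs.default_time_grid()))
    print(f"  CD {cd:4.0f} nm: peak {mm.peak:.4f} at {mm.time_to_peak_us:5.1f} us")
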