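"""Competing calcium buffers reshape the sensor occupancy.

Each buffer is a homogeneous reactive medium that captures free Ca2+
(switching its diffusion coefficient and blocking sensor binding) and
releases it again.  ATP is fast but dilute, EGTA slow but concentrated,
and the endogenous fixed buffer (EFB) both dilute's the peak and shifts
it earlier because captured ions are immobilized.
"""

import calsensor as cs

grid = cs.default_time_grid()
print("buffer   peak      t_peak(us)  steady state")
for name in (None, "EFB", "ATP", "EGTA"):
    cfg = cs.default_config([name] if name else [])
    m = cs.curve_metrics(cs.occupancy_single(cfg, grid))
    print(f"{name or 'none':6}  {m.peak:.5f}   {m.time_to_peak_us:6.2f}     {m.steady_state:.2e}")

print()
print("The fixed buffer (4 mM EFB) cuts the peak by ~40% and advances it;")
print("0.2 mM ATP and 10 mM EGTA only shave the peak, but EGTA's high")
print("affinity wipes out the steady state (it wins every ion eventually).")
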