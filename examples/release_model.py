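"""Five-site cooperative release sensor and the cost of ignoring unbinding.

The fusion sensor binds up to five Ca2+ ions (forward rates (5-i) k_on
[Ca], backward rates (i+1) k_off b^i with b = 0.25) and fuses from the
fully occupied state at gamma = 6/ms.  Setting every k_off to zero — the
pure first-passage idealization — inflates the release probability, and
the inflation grows as the calcium transient weakens.
"""

import calsensor as cs

params = cs.ReleaseParams()  # k_on=127/mM/ms, k_off=15.7/ms, b=0.25, gamma=6/ms
print("amplitude(uM)  F_control   F_no-unbinding   ratio   rate FWHM change")
for amp_mM in (0.04, 0.02, 0.01):
    ca = cs.gaussian_transient(amplitude_mM=amp_mM, fwhm=0.3)
    ctl = cs.integrate_release(params, ca)
    ko = cs.integrate_release(params, ca, knockout_koff=True)
    m = cs.release_metrics(ko, reference=ctl)
    fw = m.get("fwhm_change_percent")
    print(f"{amp_mM * 1e3:11.0f}    {ctl.fused[-1]:.4f}      {ko.fused[-1]:.4f}     "
          f"{m['release_probability_ratio']:6.2f}   "
          f"{fw:+.0f}%" if fw is not None else "    n/a")
print()
print("Weaker transients make unbinding relatively more important: the")
print("no-unbinding model overestimates release severalfold at low calcium.")
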