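# Reference biophysical parameters of the diffusion-reaction model.
# Lengths in nm, diffusion coefficients in um^2/ms, bimolecular rate
# constants in mM^-1 ms^-1, first-order rates in ms^-1, concentrations in mM.
R: 300.0
rho: 5.0
CD: 15.0
D0: 0.22
k_on: 635.0        # 5 * 127, single binding site of the five-site sensor
k_off: 15.7
area_convention: sphere
buffers:
  - name: EFB      # endogenous fixed buffer
    D: 0.0
    k_on: 100.0
    c: 4.0
    k_off: 10.0
  - name: ATP      # fast, low-affinity mobile buffer
    D: 0.2
    k_on: 100.0
    c: 0.2
    k_off: 10.0
  - name: EGTA     # slow, high-affinity mobile chelator
    D: 0.22
    k_on: 10.5
    c: 10.0
    k_off: 0.000735
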