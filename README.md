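# calsensor

Analytical and particle-based modeling of diffusion-influenced,
**reversible** Ca²⁺ binding to the vesicle-fusion sensor of a presynaptic
bouton.

Neurotransmitter release is triggered when calcium ions, entering through
voltage-gated channels tens of nanometres from a synaptic vesicle, diffuse
to and bind a fusion sensor — while competing buffers (ATP, EGTA,
endogenous fixed buffers) intercept them on the way. `calsensor` computes
the **occupancy probability** `P(t, r)`: the probability that a single ion
released at radius `r` is bound to the sensor at time `t`, with both the
forward (`k_on`) and backward (`k_off`) rate constants of the sensor taken
into account, and extends it to many ions, stochastic channel gating, and
a five-site cooperative release model. It is aimed at computational
neuroscientists and biophysicists who need sub-microsecond-to-second
occupancy curves in seconds of CPU time instead of cluster-scale
particle simulations.

## Model

The active zone is a reflecting hemisphere of radius `R` (default 300 nm)
with a partially absorbing hemispherical sensor of radius `ρ` (5 nm) at
its centre; by mirror symmetry the problem reduces to a spherical shell
`ρ < r < R`. The ion performs *switching diffusion*: it is either free
(diffusivity `D₀`) or bound to buffer `i` (diffusivity `Dᵢ`, unable to
react), with first-order exchange rates `k₀ᵢ = k_on,ᵢ·cᵢ` and `kᵢ₀`.
The survival probabilities `Sᵢ(t, r)` obey coupled backward Kolmogorov
equations with a Robin condition at the sensor,

    −D₀ ∂ₙS₀ = k_on S₀ / (N_A · 4πρ²)   at r = ρ,

and reflecting conditions elsewhere. A renewal argument converts the
first-binding-time density `ψ₁ = −∂ₜS₀` into the occupancy via its
Laplace transform:

    P̃(p, r) = ψ̃₁(p, r) / [ p + k_off (1 − ψ̃(p)) ],     ψ̃(p) = ψ̃₁(p, ρ).

The inverse transform is evaluated two independent ways:

* **Residue series** — the exact spectral representation
  `P(t,r) = P∞ + Σₙ cₙ(r) e^{−αₙ² D₀ t/ρ²}`, with closed-form
  coefficients in the buffer-free case (roots `αₙ` of a trigonometric
  secular equation in the dimensionless groups `β = (R−ρ)/ρ`,
  `λ = k_off ρ²/D₀`, `μ = k_on/(4πρD₀N_A)`) and numerically located poles
  for any number of buffers.
* **Fixed-Talbot contour inversion** — an independent numerical backend
  used as the cross-validation oracle (the two agree to better than 10⁻⁶
  across seven decades of time).

Extensions: `P_N = 1 − (1−P)^N` for `N` simultaneous ions,
binomial tails for at-least-`n`-bound, Poisson-binomial products over
stochastic channel-driven entry times, a Brownian-dynamics particle
validator, and the five-site release chain
`V₀ ⇌ … ⇌ V₅ → F` (rates `(5−i)k_on[Ca]`, `(i+1)k_off bⁱ`, fusion `γ`).

## Worked example

```python
import calsensor as cs

cfg = cs.default_config()                 # reference parameters, CD = 15 nm
curve = cs.occupancy_single(cfg, cs.default_time_grid())
m = cs.curve_metrics(curve)
print(m.peak, m.time_to_peak_us, m.steady_state)
```

prints

```
0.012113704923859561 10.811001461447448 0.0005934921524272069
```

— a single ion released 15 nm from the sensor has at most a 1.2% chance
of being bound, the maximum occurring 10.8 µs after entry, and the
long-time occupancy settles at 5.9·10⁻⁴ once the ion has equilibrated
over the bouton volume. Adding the 4 mM endogenous fixed buffer
(`cs.default_config(["EFB"])`) lowers the peak to 0.0073 and advances it
to 4.8 µs. The scripts in `examples/` walk through each capability
(buffers, multi-ion influx, channel gating, particle validation, the
release model) and print annotated numbers.

There is also a thin command line, e.g.

```bash
calsensor occupancy --cd 5,45,95 --out sweep/
calsensor release my_transient.csv --knockout --out release/
```

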