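# Methods

## The model and its assumptions

A presynaptic active zone is idealized as a reflecting hemisphere of
radius `R` centred on a hemispherical Ca²⁺ sensor of radius `ρ`; a
calcium ion enters on the membrane plane at radial distance `r` from the
centre (coupling distance `CD = r − ρ`). Mirror symmetry across the
membrane makes the hemisphere problem identical to a full spherical
shell `ρ < |x| < R`, which is what the solver uses. The ion is a point
Brownian particle (electrostatics screened, no extrusion, no baseline
calcium); each buffer is a *homogeneous reactive medium* in its linear
regime, so buffering is a Markovian state switch of the ion (free ↔
bound-to-buffer-i) with pseudo-first-order capture rate `k₀ᵢ = k_on,ᵢ cᵢ`
and release rate `kᵢ₀`, not an explicit second species. Sensor binding
is reversible with unlimited capacity: successive binding events are
independent, which is what makes the multi-ion formulas exact and is
also the model's main idealization (see Limitations).

Internal units are (nm, ms, mM) so the reference parameter values are
stored verbatim; Avogadro's number is carried explicitly, and the
bimolecular conversion is 1 mM⁻¹ms⁻¹ = 10²⁷/N_A ≈ 1660.54 nm³/ms per
ion.

### Parameters (defaults)

| symbol | meaning | default | unit |
|---|---|---|---|
| `R` | bouton (domain) radius | 300 | nm |
| `ρ` | sensor radius | 5 | nm |
| `CD` | source–sensor coupling distance | 15 | nm |
| `D₀` | free Ca²⁺ diffusivity | 0.22 | µm²/ms |
| `k_on` | sensor forward constant (5 × single-site 127) | 635 | mM⁻¹ms⁻¹ |
| `k_off` | sensor backward constant | 15.7 | ms⁻¹ |
| EFB | fixed buffer: D=0, k_on=100, c=4, k_off=10 | | |
| ATP | mobile buffer: D=0.2 µm²/ms, k_on=100, c=0.2, k_off=10 | | |
| EGTA | mobile chelator: D=0.22 µm²/ms, k_on=10.5, c=10, k_off=7.35·10⁻⁴ | | |

## The sensor area convention

The Robin constant is `κ = k_on/(N_A·a·πρ²)` with `a = 4` ("sphere",
default) or `a = 2` ("hemisphere"). The published account of this model
is internally inconsistent by a factor of two: its occupancy peaks
(0.027 at CD 5 nm, 0.012 at 15 nm, 0.001 at 95 nm) are reproduced by the
spherical convention — the Robin condition exactly as written with the
full sphere area — whereas its order-of-magnitude steady states (1·10⁻³
at R = 300 nm, 3·10⁻⁴ at 500 nm) correspond to distributing the same
`k_on` over the hemispherical area (equivalently, halving the accessible
volume in the equilibrium formula). We default to the spherical
convention because it is the literal reading of the boundary condition
and reproduces the two-significant-figure peak values; the hemispherical
convention is retained as `area_convention="hemisphere"` and the
steady-state formula follows whichever convention is configured. Both
conventions differ only by `k_on → 2k_on`.

## Laplace-domain solution

Writing `gᵢ = S̃ᵢ − 1/p`, the transformed survival system becomes a
constant-coefficient radial ODE system `Δg = W(p) g`. Fixed buffers
(`Dᵢ = 0`) are eliminated exactly,
`S̃ᵢ = (1 + kᵢ₀S̃₀)/(p + kᵢ₀)`, contributing `k₀ᵢ·p/(p + kᵢ₀)` to the
free state's effective rate; mobile buffers are handled by
diagonalizing `W`. Each eigenmode `q²ₘ` contributes two radial
solutions; these are represented by the scaled pair
`e^{−q(r−ρ)}/r, e^{−q(R−r)}/r` when `|q|(R−ρ) ≥ ½` (well conditioned at
arbitrarily large `|q|R`) and by the `cosh/sinhc` pair below that
threshold (the exponential pair degenerates towards `1/r` twice over as
`q → 0`, which would otherwise lose ~6 digits near the steady-state
limit). The boundary system (no-flux rows at `R` and at `ρ` for buffer
states, the Robin row for the free state) is solved directly; `k_on = ∞`
is supported as an exact Dirichlet row.

## Returning to the time domain

`P̃(p,r) = ψ̃₁/(p + k_off(1−ψ̃))` is meromorphic with simple poles on
the closed negative real axis (the switching generator satisfies
detailed balance, hence is symmetrizable and has a real spectrum).

**Buffer-free case.** The poles are `pₙ = −αₙ²D₀/ρ²` with `αₙ` the
positive roots of the trigonometric secular equation in `(β, λ, μ)`;
amplitudes come from the closed-form coefficient `bₙ` and the mode shape
`u(αₙ, r)`. Roots are bracketed by a scan at 40 points per asymptotic
spacing `π/β` and polished by Brent's method; every root is verified
against the cleared equation to a scale-free residual below 10⁻¹², and
near-tangent sign changes (candidate double roots) raise an error
rather than guessing — the numerical backend is the documented fallback.

**Buffered case.** Poles are located as zeros of the real secular
function `G(p) = det A(p) · F(p)/p`, where `F = p(1 + k_off S̃₀(p,ρ))`
and `A` is the boundary matrix in a real basis (eigenvalues of `W` are
real, so oscillatory modes use a `cos/sinc` pair). Multiplying by
`det A` removes the poles of `S̃₀` — each of which sits within
`k_off·(residue)` of a zero of `F`, far too close for naive scanning —
and dividing by `p` removes the trivial zero. The scan is uniform in
`s = √(−p)` at 25 points per asymptotic pole spacing of the fastest
family, with three refinements: log-spaced points near `p = 0` for slow
modes, a grid mapped through the single-buffer dispersion relation for
the eigenvalue accumulation of fixed buffers at `p = −kᵢ₀`, and
recursive subdivision of non-crossing dips of `|G|` (near-degenerate
pole pairs, e.g. when a buffer's diffusivity nearly equals `D₀`),
gated on the dip actually deepening and a global evaluation budget.
Residues use the identity `res = −[det A · g₀(r)]/G'(pₙ)`: the adjugate
product stays accurate even though the plain boundary solve is
ill-conditioned next to an eigenvalue; `G'` is a centred difference
whose step shrinks until the one-sided slopes agree.

**Numerical backend.** An independent fixed-Talbot contour (36 nodes —
the double-precision optimum between contour truncation and the
`e^{2M/5}` cancellation amplification; ~10⁻⁹ absolute accuracy on
probability-scale transforms) inverts `P̃` directly. It shares no code
with the residue path and cross-validates it in the test-suite to
<10⁻⁶ absolute over seven decades (10⁻⁷ s to 1 s) for the buffer-free,
mobile-buffer and fixed-buffer configurations. This cross-check is also
the guard against hypothetically missed (complex) poles; with a
symmetrizable generator none are expected, and no argument-principle
contour accounting is performed. A buffered configuration with
`k_off = 0` has poles that are not zeros of `F`; the series constructor
refuses it and the numeric backend is used.

The `auto` curve backend uses the residue series with enough terms that
the fastest retained rate satisfies `rate·t_min ≈ 40`, and falls back to
contour inversion for extremely small times or unsupported corners.

## Multi-ion and channel-driven occupancy

With unlimited capacity, ions are independent: `P_N = 1 − (1−P)^N`, and
the at-least-`n` probability is the survival function of
`Binomial(N, P)` (evaluated by `scipy.stats.binom.sf`, stable for large
`N`). For distributed entry times the per-trial curve is
`1 − Πᵢ(1 − P(t − tᵢ))`, with entries later than `t` contributing
nothing — the elapsed-time reading is the only causal one. The Gaussian
entry fixture (defaults `N = 200`, FWHM 0.3 ms) emulates the
action-potential-driven influx through one channel.

The channel itself is a sequential three-gate chain (closed⁰…closed² →
open) with exponential voltage dependence `α = a₀e^{V/kₐ}`,
`β = b₀e^{−V/k_b}` and a linear driving-force open-channel current. The
published constraints — opening probability 0.3 per action potential,
peak open-channel current 0.3 pA, mean-current FWHM 250 µs — do not pin
down every rate constant, so `calibrate_gating` tunes the two prefactors
(Nelder–Mead on the master equation, which is deterministic and fast)
and rescales the conductance analytically; the voltage slopes (25 and
18 mV) and the stylized Gaussian action potential (110 mV over −70 mV
baseline, 0.35 ms FWHM) are fixed choices representative of fast
presynaptic waveforms. Stochastic trials use exact jump times via
thinning; ion entries are an inhomogeneous Poisson process with
intensity `i(V)/2e` during open periods.

## Particle-based validator

Ions take Gaussian steps with the state-dependent diffusivity
(default `dt` 5 ns, with 20 ns used in the scaled-down test runs);
buffer capture/release are per-step Markov transitions decided from the
state at the step start; the membrane plane reflects by `|z|` mirroring
and the outer sphere by radial fold-back, iterated. A step ending
inside the sensor is accepted as binding with the standard
Brownian-dynamics Robin discretization `P_bind = κ√(π dt/D₀)`
(converging to the Robin condition with an `O(√dt)` surface bias),
otherwise reflected radially; bound ions draw an exponential `k_off`
residence time and restart on the sensor surface. For the perfect
absorber (`k_on = ∞`, acceptance probability 1) a Brownian-bridge touch
probability `exp(−d_prev·d_now/(D dt))` supplements endpoint crossing
detection, removing most of the contact-detection bias. Sensor capacity
may be unlimited (the analytic assumption), a single site, or `k` sites;
with finite capacity, simultaneous attempts are granted first come,
first served.

Reproducibility: one seeded PCG64 generator drives the trial-vectorized
simulation, so a run is bit-reproducible given `(seed, n_trials)`;
per-trial streams independent of the trial count were traded for the
large speedup of vectorizing across trials.

## Five-site release model

`V₀ ⇌ … ⇌ V₅ → F` with forward rates `(5−i)k_on[Ca](t)`, backward rates
`(i+1)k_off bⁱ` (the printed exponent convention `b⁰…b⁴` is followed
literally), fusion `γ` from `V₅`. Defaults `k_on = 127 mM⁻¹ms⁻¹`,
`k_off = 15.7 ms⁻¹`, `b = 0.25`, `γ = 6 ms⁻¹`. The transient `[Ca](t)`
is exogenous and piecewise linear (the sensor does not deplete calcium).
The default integrator is LSODA at `rtol 10⁻¹²`; the fused fraction is
computed as `F = 1 − ΣVᵢ`, making conservation exact by construction,
with a monotone accumulation step absorbing sub-10⁻¹³ integrator
wiggles. A forward-Euler compatibility mode (with an explicit stability
guard `dt·max_rate < 0.1`) reproduces the historical integration scheme.
The published knockout ratios (2.4×, 7-fold, +61% half-width) depend on
unpublished finite-element calcium transients; the package treats them
as directional properties on synthetic Gaussian transients — the
knockout/control release ratio exceeds 1 and grows as the transient
weakens — not as numerical targets.

## What the synthetic data do and do not show

The generators (Gaussian entry fixture, stylized action potential,
Gaussian calcium transients) reproduce the *statistical shape* of the
published inputs — ion counts, time courses, channel characteristics —
but not the spatial heterogeneity of a real active zone: multi-channel
cluster geometry, vesicle crowding, or finite-element calcium
landscapes. Tests passing on these inputs demonstrate the correctness
of the mathematics (transforms, inversion, simulation schemes) and the
stated qualitative directions, not quantitative agreement with any
particular synapse.

## Numerical choices and degenerate inputs

* `k_on = 0` short-circuits to exact zeros everywhere; `k_off = 0` makes
  the occupancy a first-passage CDF (monotone); `k_on = ∞` switches the
  Robin row to Dirichlet.
* A buffer with `c = 0` (or `k₀ᵢ = 0`) is algebraically inert and the
  solution coincides with the bufferless one to machine precision.
* Curve metrics refine the grid maximum by a log-time quadratic fit;
  FWHM is measured against a zero baseline and reported absent for
  monotone curves; the departure time `t_c` against a reference curve
  uses a 1% relative threshold (the qualitative "start to deviate" has
  no published quantitative definition).
* Nearly coincident poles are merged below 10⁻¹² relative separation;
  their unresolved tail weight is bounded by the Talbot cross-check.

## Problem sizes

The default analytic grid is 600 log-spaced points over 10⁻⁴–10³ ms
(seconds per curve including the pole search). The validation
simulations in the test-suite use 10⁴ single-ion trials at `dt = 20 ns`
over a 0.12 ms horizon, 250 trials of 50 ions for the saturation
direction, and ~10³-trial channel ensembles; these sizes put every
statistical comparison at the 3-SEM level while keeping the whole suite
in a few minutes.

## Known limitations

* Unlimited sensor capacity in the analytic path: accuracy of `P_N`
  degrades when the predicted occupancy approaches 1 (saturation is
  available only in the particle validator).
* The particle validator's surface-reaction rule carries an `O(√dt)`
  bias for partially absorbing sensors; the bridge correction applies
  only to the perfect absorber.
* No buffer-to-buffer exchange, calcium extrusion, baseline calcium, or
  sensor-driven calcium depletion.
* The channel calibration fixes the published three characteristics but
  the underlying rate constants are not unique; quantities conditional
  on the exact open-time distribution inherit this freedom.
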