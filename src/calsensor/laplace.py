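"""Laplace-domain solution of the switching-diffusion survival problem.

A Ca2+ ion diffuses in the spherical shell ``rho < r < R`` and switches
between a free state (index 0, diffusivity D0) and ``M`` buffer-bound
states (index i, diffusivity D_i), with pseudo-first-order exchange rates
k_0i (capture) and k_i0 (release); bound states cannot react with the
sensor.  The survival probabilities S_i(t, r) — the probability that an
ion started at radius r in state i has not yet bound to the sensor —
satisfy coupled backward Kolmogorov equations with a Robin condition for
the free state at the sensor surface and Neumann conditions elsewhere.

In the Laplace domain the system reduces to a set of radial modified
Helmholtz equations.  Writing g_i = S~_i - 1/p, the constant 1/p is a
particular solution and the homogeneous part satisfies

    Delta g = W(p) g,      W diagonalizable with eigenvalues q_m^2.

Fixed buffers (D_i = 0) are eliminated algebraically,
S~_i = (1 + k_i0 S~_0) / (p + k_i0), which folds into a p-dependent
effective rate for the free state.  Mobile buffers are handled by
diagonalizing W.  Each radial mode contributes exp(+-q r)/r solutions;
the exponentials are kept in the scaled forms exp(-q(r-rho))/r and
exp(-q(R-r))/r so the boundary linear system stays well conditioned for
arbitrarily large |q| R.

The renewal identity then converts survival into sensor occupancy:

    psi~_1(p, r) = 1 - p S~_0(p, r)           (first-binding density)
    psi~(p)      = psi~_1(p, rho)             (re-binding density)
    P~(p, r)     = psi~_1(p, r) / (p + k_off (1 - psi~(p))).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig

__all__ = [
    "SurvivalLaplace",
    "OccupancyLaplace",
    "NumericalDegeneracyError",
    "solve_survival",
    "survival_free",
    "occupancy_laplace",
    "occupancy_laplace_value",
]


class NumericalDegeneracyError(ArithmeticError):
    """The boundary-condition linear system is singular for these parameters."""


@dataclass(frozen=True)
class SurvivalLaplace:
    """Laplace-transformed survival probabilities at one (p, r)."""

    p: complex
    r: float
    S0: complex
    S_buffers: tuple[complex, ...] = ()


@dataclass(frozen=True)
class OccupancyLaplace:
    """Laplace-transformed occupancy probability at one (p, r)."""

    p: complex
    r: float
    P: complex
    psi1: complex
    psi: complex


def _sqrt_principal(z: complex) -> complex:
    q = cmath.sqrt(z)
    if q.real < 0:
        q = -q
    return q


def _sinhc(x: complex) -> complex:
    """sinh(x)/x, stable at small |x|."""
    if abs(x) < 1e-8:
        return 1.0 + x * x / 6.0
    return cmath.sinh(x) / x


def _mode_basis(q: complex, r: float, rho: float, R: float):
    """Scaled radial solutions of g'' + (2/r) g' = q^2 g and their derivatives.

    For |q|(R - rho) >= 1/2 the exponential pair
    f1 = exp(-q (r - rho))/r (decays away from the sensor) and
    f2 = exp(-q (R - r))/r (decays away from the outer wall); for smaller
    |q| the pair degenerates towards 1/r twice over, so the
    well-conditioned cosh/sinhc pair is used instead.
    """
    if abs(q) * (R - rho) < 0.5:
        x = q * (r - rho)
        ch, sh = cmath.cosh(x), cmath.sinh(x)
        f1 = ch / r
        f2 = (r - rho) * _sinhc(x) / r
        f1p = q * sh / r - ch / r**2
        f2p = ch / r - f2 / r
        return f1, f2, f1p, f2p
    e1 = cmath.exp(-q * (r - rho))
    e2 = cmath.exp(-q * (R - r))
    f1 = e1 / r
    f2 = e2 / r
    return f1, f2, (-q - 1.0 / r) * f1, (q - 1.0 / r) * f2


def _effective_free_rate(p: complex, config: ModelConfig) -> complex:
    """p plus the contributions of all fixed buffers and mobile capture rates.

    Fixed buffer i contributes p k_0i / (p + k_i0); mobile buffer j
    contributes its capture rate k_0j (the release enters through the
    coupling matrix).
    """
    rate = p
    for b in config.buffers:
        k0i, ki0 = b.binding_rate, b.unbinding_rate
        if b.is_fixed:
            rate = rate + k0i * p / (p + ki0)
        else:
            rate = rate + k0i
    return rate


def _solve_modes(p: complex, config: ModelConfig):
    """Solve the boundary-condition system; return (modes, V, coeffs).

    ``modes`` are the eigen-wavenumbers q_m, ``V`` the (n_states x n_modes)
    eigenvector matrix over (free, mobile buffers), ``coeffs`` the per-mode
    (A_m, B_m) amplitudes of the scaled radial basis.
    """
    rho, R = config.geometry.rho, config.geometry.R
    D0, kappa = config.D0, config.kappa
    mobile = [b for b in config.buffers if not b.is_fixed]
    n = 1 + len(mobile)

    if n == 1:
        q = _sqrt_principal(_effective_free_rate(p, config) / D0)
        qs = np.array([q])
        V = np.ones((1, 1), dtype=complex)
    else:
        W = np.zeros((n, n), dtype=complex)
        W[0, 0] = _effective_free_rate(p, config) / D0
        for j, b in enumerate(mobile, start=1):
            W[0, j] = -b.binding_rate / D0
            W[j, 0] = -b.unbinding_rate / b.D
            W[j, j] = (p + b.unbinding_rate) / b.D
        ev, V = np.linalg.eig(W)
        qs = np.array([_sqrt_principal(z) for z in ev])

    A = np.zeros((2 * n, 2 * n), dtype=complex)
    rhs = np.zeros(2 * n, dtype=complex)
    # no-flux at the outer wall for every state
    for i in range(n):
        for m in range(n):
            _, _, f1p, f2p = _mode_basis(qs[m], R, rho, R)
            A[i, 2 * m] = V[i, m] * f1p
            A[i, 2 * m + 1] = V[i, m] * f2p
    # Robin condition for the free state at the sensor:
    # D0 g0'(rho) - kappa g0(rho) = kappa / p ; in the perfectly
    # absorbing limit kappa = inf this degenerates to Dirichlet
    # S~_0(rho) = 0, i.e. g0(rho) = -1/p
    for m in range(n):
        f1, f2, f1p, f2p = _mode_basis(qs[m], rho, rho, R)
        if math.isinf(kappa):
            A[n, 2 * m] = V[0, m] * f1
            A[n, 2 * m + 1] = V[0, m] * f2
        else:
            A[n, 2 * m] = V[0, m] * (D0 * f1p - kappa * f1)
            A[n, 2 * m + 1] = V[0, m] * (D0 * f2p - kappa * f2)
    rhs[n] = -1.0 / p if math.isinf(kappa) else kappa / p
    # no-flux at the sensor for mobile buffer states
    for j in range(1, n):
        for m in range(n):
            _, _, f1p, f2p = _mode_basis(qs[m], rho, rho, R)
            A[n + j, 2 * m] = V[j, m] * f1p
            A[n + j, 2 * m + 1] = V[j, m] * f2p
    try:
        coeffs = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(
            f"singular boundary system at p={p!r} (M={config.M})"
        ) from exc
    if not np.all(np.isfinite(coeffs)):
        raise NumericalDegeneracyError(f"non-finite boundary solution at p={p!r}")
    return qs, V, coeffs


def _g_states(p: complex, r: float, config: ModelConfig):
    """Homogeneous parts g_i(r) = S~_i - 1/p for free + mobile states."""
    rho, R = config.geometry.rho, config.geometry.R
    qs, V, coeffs = _solve_modes(p, config)
    n = len(qs)
    g = np.zeros(n, dtype=complex)
    for m in range(n):
        f1, f2, _, _ = _mode_basis(qs[m], r, rho, R)
        g += V[:, m] * (coeffs[2 * m] * f1 + coeffs[2 * m + 1] * f2)
    return g


def survival_free(p: complex, r: float, config: ModelConfig) -> complex:
    """Laplace-transformed survival probability S~_0(p, r) of a free ion.

    With a non-reactive sensor (k_on = 0) this is exactly 1/p.
    """
    if config.sensor.k_on == 0.0:
        return 1.0 / p
    return _g_states(p, r, config)[0] + 1.0 / p


def solve_survival(config: ModelConfig, p: complex, r: float) -> SurvivalLaplace:
    """Solve the switching-diffusion survival problem at one (p, r).

    Returns S~_i(p, r) for the free state and every buffer state, in the
    order of ``config.buffers``.  Fixed-buffer values are recovered from
    the algebraic elimination S~_i = (1 + k_i0 S~_0)/(p + k_i0).
    """
    rho = config.geometry.rho
    if not (rho < r <= config.geometry.R):
        raise ValueError(f"radius r={r} outside the shell ({rho}, {config.geometry.R}]")
    if config.sensor.k_on == 0.0:
        inv_p = 1.0 / p
        return SurvivalLaplace(p=p, r=r, S0=inv_p, S_buffers=(inv_p,) * config.M)
    g = _g_states(p, r, config)
    S0 = g[0] + 1.0 / p
    S_buf = []
    mobile_idx = 1
    for b in config.buffers:
        if b.is_fixed:
            S_buf.append((1.0 + b.unbinding_rate * S0) / (p + b.unbinding_rate))
        else:
            S_buf.append(g[mobile_idx] + 1.0 / p)
            mobile_idx += 1
    return SurvivalLaplace(p=p, r=r, S0=S0, S_buffers=tuple(S_buf))


def occupancy_laplace_value(config: ModelConfig, p: complex, r: float) -> complex:
    """P~(p, r) = psi~_1(p, r) / (p + k_off (1 - psi~(p)))."""
    if config.sensor.k_on == 0.0:
        return 0.0 + 0.0j
    rho = config.geometry.rho
    psi1 = 1.0 - p * survival_free(p, r, config)
    if r == rho:
        psi = psi1
    else:
        psi = 1.0 - p * survival_free(p, rho, config)
    return psi1 / (p + config.sensor.k_off * (1.0 - psi))


def occupancy_laplace(config: ModelConfig, p: complex, r: float | None = None) -> OccupancyLaplace:
    """Full Laplace-domain occupancy record at one (p, r)."""
    if r is None:
        r = config.geometry.r
    rho = config.geometry.rho
    if config.sensor.k_on == 0.0:
        return OccupancyLaplace(p=p, r=r, P=0j, psi1=0j, psi=0j)
    psi1 = 1.0 - p * survival_free(p, r, config)
    psi = psi1 if r == rho else 1.0 - p * survival_free(p, rho, config)
    P = psi1 / (p + config.sensor.k_off * (1.0 - psi))
    return OccupancyLaplace(p=p, r=r, P=P, psi1=psi1, psi=psi)


def _real_mode_basis(w: float, r: float, rho: float, R: float):
    """Real radial basis for eigenvalue w = q^2 of the coupling matrix.

    For w > 0 the scaled exponential pair, for w < 0 the oscillatory pair
    sin(k (r - rho))/r, cos(k (r - rho))/r with k = sqrt(-w).  Returns
    (f1, f2, f1', f2').
    """
    if abs(w) * (R - rho) ** 2 < 0.25:
        # degenerate-pair regime: use the analytic continuation of the
        # cosh/sinhc pair (valid for either sign of w)
        out = _mode_basis(cmath.sqrt(complex(w)), r, rho, R)
        return tuple(v.real for v in out)
    if w > 0.0:
        q = math.sqrt(w)
        e1 = math.exp(-q * (r - rho))
        e2 = math.exp(-q * (R - r))
        f1, f2 = e1 / r, e2 / r
        return f1, f2, (-q - 1.0 / r) * f1, (q - 1.0 / r) * f2
    # oscillatory pair, ordered to continue the cosh/sinhc pair smoothly
    k = math.sqrt(-w)
    s, c = math.sin(k * (r - rho)), math.cos(k * (r - rho))
    f1, f2 = c / r, s / (k * r)
    return f1, f2, -k * s / r - c / r**2, c / r - s / (k * r**2)


def _real_W(p: float, config: ModelConfig):
    """Real coupling matrix over (free, mobile buffers) at real p.

    Returns (W, blocked) where ``blocked`` flags p sitting exactly on a
    fixed-buffer elimination pole p = -k_i0.
    """
    mobile = [b for b in config.buffers if not b.is_fixed]
    n = 1 + len(mobile)
    eff = p
    for b in config.buffers:
        if b.is_fixed:
            if p == -b.unbinding_rate:
                return None, True
            eff += b.binding_rate * p / (p + b.unbinding_rate)
        else:
            eff += b.binding_rate
    W = np.zeros((n, n))
    W[0, 0] = eff / config.D0
    for j, b in enumerate(mobile, start=1):
        W[0, j] = -b.binding_rate / config.D0
        W[j, 0] = -b.unbinding_rate / b.D
        W[j, j] = (p + b.unbinding_rate) / b.D
    return W, False


def real_boundary_system(p: float, config: ModelConfig):
    """Real boundary matrix A(p), right-hand side and mode data at real p < 0.

    The coupling matrix is similar to a symmetric matrix (detailed
    balance), so its eigenvalues are real and the radial basis can be
    chosen real; the determinant of A is then a real secular function
    whose zeros are the eigenvalues of the survival operator.
    Returns (A, rhs, qs2, V) or None at a fixed-buffer elimination pole.
    """
    rho, R = config.geometry.rho, config.geometry.R
    D0, kappa = config.D0, config.kappa
    W, blocked = _real_W(p, config)
    if blocked:
        return None
    n = W.shape[0]
    if n == 1:
        w2 = np.array([W[0, 0]])
        V = np.ones((1, 1))
    else:
        ev, V = np.linalg.eig(W)
        if np.max(np.abs(ev.imag)) > 1e-9 * np.max(np.abs(ev.real) + 1.0):
            raise NumericalDegeneracyError(f"complex coupling eigenvalues at p={p}")
        w2 = ev.real
        V = V.real
    A = np.zeros((2 * n, 2 * n))
    rhs = np.zeros(2 * n)
    for i in range(n):
        for m in range(n):
            _, _, f1p, f2p = _real_mode_basis(w2[m], R, rho, R)
            A[i, 2 * m] = V[i, m] * f1p
            A[i, 2 * m + 1] = V[i, m] * f2p
    for m in range(n):
        f1, f2, f1p, f2p = _real_mode_basis(w2[m], rho, rho, R)
        A[n, 2 * m] = V[0, m] * (D0 * f1p - kappa * f1)
        A[n, 2 * m + 1] = V[0, m] * (D0 * f2p - kappa * f2)
    rhs[n] = kappa / p
    for j in range(1, n):
        for m in range(n):
            _, _, f1p, f2p = _real_mode_basis(w2[m], rho, rho, R)
            A[n + j, 2 * m] = V[j, m] * f1p
            A[n + j, 2 * m + 1] = V[j, m] * f2p
    return A, rhs, w2, V


def pole_indicator(config: ModelConfig, p: float, radii=()):
    """Real secular function G(p) = det(A) F(p) / p and auxiliary data.

    F(p) = p (1 + k_off S~_0(p, rho)) is the pole-generating denominator;
    multiplying by det(A)/p removes both the survival-operator poles and
    the trivial zero at p = 0, leaving a smooth real function whose sign
    changes locate the occupancy poles.  Also returns det(A) and the
    products det(A) * g0(r) for each requested radius (stable even next
    to an eigenvalue), used for residue evaluation.
    """
    sys_ = real_boundary_system(p, config)
    if sys_ is None:
        return None
    A, rhs, w2, V = sys_
    sign, logdet = np.linalg.slogdet(A)
    if sign == 0.0:
        return None
    det = sign * math.exp(logdet)
    try:
        coeffs = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return None
    rho, R = config.geometry.rho, config.geometry.R
    koff = config.sensor.k_off

    def g0_at(r):
        tot = 0.0
        for m in range(len(w2)):
            f1, f2, _, _ = _real_mode_basis(w2[m], r, rho, R)
            tot += V[0, m] * (coeffs[2 * m] * f1 + coeffs[2 * m + 1] * f2)
        return tot

    g0_rho = g0_at(rho)
    # G = det * F / p = det * (1 + koff/p) + koff * det * g0(rho)
    G = det * (1.0 + koff / p) + koff * det * g0_rho
    det_g0 = {float(r): det * g0_at(r) for r in radii}
    return G, det, det_g0


def rebinding_denominator(config: ModelConfig, p: complex) -> complex:
    """F(p) = p + k_off (1 - psi~(p)), the pole-generating denominator.

    Zeros of F on the closed negative real axis are the poles of P~; the
    zero at p = 0 carries the steady-state residue.
    """
    rho = config.geometry.rho
    psi = 1.0 - p * survival_free(p, rho, config)
    return p + config.sensor.k_off * (1.0 - psi)
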