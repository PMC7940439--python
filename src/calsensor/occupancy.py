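"""User-facing occupancy curves, multi-ion extensions and curve metrics."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom

from .config import ModelConfig
from .inversion import occupancy_values
from .inversion import steady_state as _steady_state

__all__ = [
    "OccupancyCurve",
    "CurveMetrics",
    "default_time_grid",
    "occupancy_single",
    "steady_state",
    "occupancy_at_least_one",
    "occupancy_at_least_n",
    "curve_metrics",
    "curve_error_metrics",
]


def default_time_grid(n: int = 600, t_min: float = 1e-4, t_max: float = 1e3) -> np.ndarray:
    """Log-spaced time grid in ms (default 0.1 us .. 1 s)."""
    return np.logspace(math.log10(t_min), math.log10(t_max), n)


@dataclass(frozen=True)
class OccupancyCurve:
    """A sensor occupancy probability curve P(t) on a fixed time grid.

    ``provenance`` records which backend produced the values
    ("series", "numeric", "auto", "mc", "transform").
    """

    times: np.ndarray
    values: np.ndarray
    provenance: str = "auto"
    config: ModelConfig | None = None
    sem: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((v < -1e-9) | (v > 1 + 1e-9)):
            raise ValueError("occupancy values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def interp(self, t) -> np.ndarray:
        """Linear interpolation of the curve (zero before the first grid point)."""
        return np.interp(t, self.times, self.values, left=0.0, right=self.values[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.times, "P": self.values})
        if self.sem is not None:
            df["sem"] = self.sem
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CurveMetrics:
    """Summary metrics of a (typically biphasic) occupancy curve.

    Peak and time-to-peak come from a local quadratic refinement in
    log-time around the grid maximum; FWHM is measured relative to a
    zero baseline.  ``t_c`` is the first time the curve deviates from a
    reference curve by more than a relative threshold.  Times in us.
    """

    peak: float
    time_to_peak_us: float | None
    fwhm_us: float | None
    steady_state: float | None = None
    t_c_us: float | None = None

    def to_dict(self) -> dict:
        return {
            "peak": self.peak,
            "time_to_peak_us": self.time_to_peak_us,
            "fwhm_us": self.fwhm_us,
            "steady_state": self.steady_state,
            "t_c_us": self.t_c_us,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=False)


def occupancy_single(
    config: ModelConfig,
    times: np.ndarray | None = None,
    backend: str = "auto",
) -> OccupancyCurve:
    """Single-ion occupancy P(t, r) at the configured source radius."""
    if times is None:
        times = default_time_grid()
    vals = occupancy_values(config, times, backend=backend)
    return OccupancyCurve(times=np.asarray(times, float), values=vals, provenance=backend, config=config)


def steady_state(config: ModelConfig) -> float:
    """Steady-state occupancy P_inf (closed form)."""
    return _steady_state(config)


def occupancy_at_least_one(P: OccupancyCurve, N: int) -> OccupancyCurve:
    """P_N(t) = 1 - (1 - P(t))^N for N ions released simultaneously.

    Assumes unlimited sensor binding capacity (independent ions).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    v = np.clip(P.values, 0.0, 1.0)
    saturated = v >= 1.0
    vals = -np.expm1(N * np.log1p(-np.where(saturated, 0.0, v)))
    vals[saturated] = 1.0
    return replace(P, values=vals, provenance="transform", sem=None)


def occupancy_at_least_n(P: OccupancyCurve, N: int, n: int) -> OccupancyCurve:
    """Binomial-tail occupancy: probability that >= n of N ions are bound.

    P_{N,n}(t) = 1 - sum_{k<n} C(N,k) P^k (1-P)^(N-k) = Pr[Bin(N, P) >= n].
    Reduces exactly to ``occupancy_at_least_one`` for n = 1.
    """
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    vals = binom.sf(n - 1, N, np.clip(P.values, 0.0, 1.0))
    return replace(P, values=vals, provenance="transform", sem=None)


def _quadratic_refine(logt: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through three points around index i (log-time)."""
    if i == 0 or i == len(v) - 1:
        return logt[i], v[i]
    x0, x1, x2 = logt[i - 1 : i + 2]
    y0, y1, y2 = v[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        return logt[i], v[i]
    xv = -b / (2 * a)
    if not (x0 <= xv <= x2):
        return logt[i], v[i]
    c = y1 - a * x1**2 - b * x1
    return xv, a * xv**2 + b * xv + c


def _half_crossings(t: np.ndarray, v: np.ndarray, half: float, i_peak: int):
    """Linear-interpolated crossings of ``half`` on either side of the peak."""
    left = None
    for i in range(i_peak, 0, -1):
        if v[i - 1] < half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    right = None
    for i in range(i_peak, len(v) - 1):
        if v[i] >= half > v[i + 1]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    return left, right


def curve_metrics(
    P: OccupancyCurve,
    reference: OccupancyCurve | None = None,
    deviation_tol: float = 0.01,
) -> CurveMetrics:
    """Peak, time-to-peak, FWHM (vs zero baseline) and optional departure time.

    For a monotone (non-biphasic) curve the FWHM is reported absent.  The
    departure time ``t_c`` is the first grid time where
    |P - P_ref| / max(P_ref) exceeds ``deviation_tol``; it requires a
    reference curve on the same grid.
    """
    t, v = P.times, P.values
    i = int(np.argmax(v))
    peak = float(v[i])
    ss = steady_state(P.config) if P.config is not None else None

    if np.all(v == v[0]):
        return CurveMetrics(peak=peak, time_to_peak_us=None, fwhm_us=None, steady_state=ss)

    logt = np.log(t)
    xv, pv = _quadratic_refine(logt, v, i)
    t_peak = math.exp(xv)
    peak = float(max(pv, peak))

    fwhm = None
    # biphasic test: the curve must come back down below half peak
    left, right = _half_crossings(t, v, peak / 2.0, i)
    if left is not None and right is not None:
        fwhm = (right - left) * 1e3

    t_c = None
    if reference is not None:
        ref = reference.interp(t)
        scale = float(np.max(ref))
        if scale > 0:
            dev = np.abs(v - ref) / scale
            hits = np.nonzero(dev > deviation_tol)[0]
            if hits.size:
                t_c = float(t[hits[0]]) * 1e3
    return CurveMetrics(
        peak=peak,
        time_to_peak_us=t_peak * 1e3,
        fwhm_us=fwhm,
        steady_state=ss,
        t_c_us=t_c,
    )


def curve_error_metrics(a: OccupancyCurve, b: OccupancyCurve) -> Mapping[str, float | None]:
    """MAE and FWHM percentage error between two curves.

    ``b`` is resampled onto ``a``'s grid by linear interpolation.  The
    FWHM error is 100 |FWHM_a - FWHM_b| / FWHM_b; absent when either
    FWHM is undefined.
    """
    bv = b.interp(a.times)
    mae = float(np.mean(np.abs(a.values - bv)))
    ma = curve_metrics(a)
    mb = curve_metrics(b)
    fwhm_err = None
    if ma.fwhm_us is not None and mb.fwhm_us:
        fwhm_err = 100.0 * abs(ma.fwhm_us - mb.fwhm_us) / mb.fwhm_us
    return {"mae": mae, "fwhm_error_percent": fwhm_err}
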