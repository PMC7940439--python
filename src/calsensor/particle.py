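"""Particle-based Brownian-dynamics validation of the analytical solution.

Ions perform Gaussian displacement steps in the hemispherical shell
(rho < |x| < R, z > 0) with a state-dependent diffusion coefficient;
buffer capture/release is per-step Markov switching against the
homogeneous-reactive-medium rates (buffers are not explicit particles,
matching the analytical model's assumptions); the membrane plane and the
outer hemisphere reflect; binding on sensor contact is accepted with the
standard Brownian-dynamics Robin discretization

    P_bind = kappa * sqrt(pi * dt / D0),

which converges to the Robin boundary condition as dt -> 0 (the residual
surface-reaction bias is O(sqrt(dt))).  Bound ions draw an exponential
residence time (rate k_off) and restart on the sensor surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig
from .influx import IonEntrySequence
from .occupancy import OccupancyCurve

__all__ = [
    "MCConfig",
    "EventLog",
    "GeometryEscapeError",
    "single_ion_trials",
    "simulate_ions",
    "estimate_occupancy",
    "empirical_fpt",
    "bound_intervals",
]

EVENT_BIND = 0
EVENT_UNBIND = 1
EVENT_CAPTURE = 2
EVENT_RELEASE = 3
EVENT_NAMES = {EVENT_BIND: "bind", EVENT_UNBIND: "unbind",
               EVENT_CAPTURE: "buffer_capture", EVENT_RELEASE: "buffer_release"}


class GeometryEscapeError(RuntimeError):
    """A particle left the domain beyond tolerance after reflection (bug trap)."""


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run settings.

    ``dt`` in ms (default 5 ns), ``horizon`` in ms, ``sensor_capacity``
    either the string ``"unlimited"`` or a positive number of sites
    (1 = single site).  ``record_buffer_events`` controls whether the
    (typically very frequent) capture/release transitions are logged.
    """

    dt: float = 5e-6
    interaction_range: float = 5.0
    n_trials: int = 1000
    horizon: float = 1.0
    seed: int | None = None
    sensor_capacity: int | str = "unlimited"
    record_buffer_events: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.horizon <= 0 or self.n_trials < 1:
            raise ValueError("dt, horizon must be positive and n_trials >= 1")
        if self.sensor_capacity != "unlimited" and int(self.sensor_capacity) < 1:
            raise ValueError("sensor_capacity must be 'unlimited' or a positive integer")

    def capacity(self) -> float:
        return math.inf if self.sensor_capacity == "unlimited" else int(self.sensor_capacity)

    def step_warning(self, config: ModelConfig) -> str | None:
        step = math.sqrt(2.0 * config.D0 * self.dt)
        cd = config.geometry.cd
        if cd > 0 and step > cd / 5.0:
            return (
                f"rms step {step:.3g} nm exceeds CD/5 = {cd / 5:.3g} nm; "
                "surface-reaction bias may be significant"
            )
        return None


@dataclass
class EventLog:
    """Binding/unbinding (and optionally buffer) events of a simulation.

    Columns: trial, ion, time (ms), event code.  Within each ion, bind
    and unbind events strictly alternate.
    """

    trial: np.ndarray
    ion: np.ndarray
    time: np.ndarray
    event: np.ndarray
    n_trials: int
    horizon: float

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "ion": self.ion,
                "time_ms": self.time,
                "event": [EVENT_NAMES[e] for e in self.event],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def select(self, *codes: int):
        m = np.isin(self.event, codes)
        return self.trial[m], self.ion[m], self.time[m]


def single_ion_trials(n_trials: int, r: float) -> list[IonEntrySequence]:
    """n_trials trials, each with a single ion released at t=0 from radius r."""
    return [
        IonEntrySequence(times=np.array([0.0]), trial=j, radii=np.array([r]))
        for j in range(n_trials)
    ]


def _reflect(pos: np.ndarray, rho: float, R: float, max_iter: int = 10) -> np.ndarray:
    """Mirror at z=0, fold back radially at the outer sphere; iterate."""
    for _ in range(max_iter):
        pos[:, 2] = np.abs(pos[:, 2])
        rr = np.linalg.norm(pos, axis=1)
        out = rr > R
        if out.any():
            scale = (2.0 * R - rr[out]) / rr[out]
            pos[out] *= scale[:, None]
        if not out.any() and np.all(pos[:, 2] >= 0):
            break
    return pos


def simulate_ions(
    config: ModelConfig,
    mc: MCConfig,
    entries: IonEntrySequence | Sequence[IonEntrySequence],
) -> EventLog:
    """Brownian-dynamics simulation of all trials' ions; returns the event log.

    ``entries`` supplies per-trial ion entry times and source radii (a
    single sequence is treated as one trial).  Ions enter on the membrane
    plane at their entry radius.  With ``sensor_capacity`` finite,
    binding attempts while the trial's sites are full are reflected.
    """
    if isinstance(entries, IonEntrySequence):
        entries = [entries]
    g = config.geometry
    rho, R = g.rho, g.R
    dt = mc.dt
    rng = np.random.default_rng(mc.seed)
    koff = config.sensor.k_off
    kappa = config.kappa
    if config.sensor.k_on == 0:
        p_bind = 0.0
    elif math.isinf(kappa):
        p_bind = 1.0
    else:
        p_bind = kappa * math.sqrt(math.pi * dt / config.D0)
        if p_bind > 1.0:
            raise ValueError(f"binding probability {p_bind:.3g} > 1: decrease dt")
    # perfect absorber: also count Brownian-bridge touches between step
    # endpoints (half-space approximation), removing most of the
    # O(sqrt(dt)) contact-detection bias of the crossing-only scheme
    bridge = math.isinf(kappa)

    # flatten (trial, ion)
    trial_ids, ion_ids, entry_times, entry_radii = [], [], [], []
    for j, seq in enumerate(entries):
        tid = seq.trial if seq.trial is not None else j
        radii = seq.radii if seq.radii is not None else np.full(len(seq), g.r)
        for i, (te, re_) in enumerate(zip(seq.times, radii)):
            trial_ids.append(tid)
            ion_ids.append(i)
            entry_times.append(te)
            entry_radii.append(re_)
    trial_ids = np.asarray(trial_ids)
    ion_ids = np.asarray(ion_ids)
    entry_times = np.asarray(entry_times)
    entry_radii = np.asarray(entry_radii)
    n = len(trial_ids)
    if n == 0:
        return EventLog(*(np.array([], dtype=int),) * 2, np.array([]), np.array([], dtype=int),
                        n_trials=len(entries), horizon=mc.horizon)

    # map trial ids to dense indices for capacity bookkeeping
    uniq_trials, trial_dense = np.unique(trial_ids, return_inverse=True)
    bound_count = np.zeros(len(uniq_trials))
    capacity = mc.capacity()

    buffers = config.buffers
    M = len(buffers)
    D_by_state = np.array([config.D0] + [b.D for b in buffers])
    k_cap = np.array([b.binding_rate for b in buffers])  # free -> i
    k_rel = np.array([b.unbinding_rate for b in buffers])  # i -> free
    p_cap_tot = -np.expm1(-k_cap.sum() * dt) if M else 0.0
    cap_weights = k_cap / k_cap.sum() if M and k_cap.sum() > 0 else None
    p_rel = -np.expm1(-k_rel * dt) if M else np.array([])

    pos = np.zeros((n, 3))
    pos[:, 0] = entry_radii
    state = np.zeros(n, dtype=np.int64)  # 0 free, 1..M buffer-bound
    alive = np.zeros(n, dtype=bool)  # entered and not sensor-bound
    bound = np.zeros(n, dtype=bool)
    unbind_at = np.full(n, np.inf)

    ev_trial, ev_ion, ev_time, ev_code = [], [], [], []

    def log_event(idx: np.ndarray, t: float | np.ndarray, code: int):
        if len(idx) == 0:
            return
        ev_trial.append(trial_ids[idx])
        ev_ion.append(ion_ids[idx])
        ev_time.append(np.broadcast_to(np.asarray(t, float), idx.shape).copy())
        ev_code.append(np.full(len(idx), code, dtype=np.int64))

    n_steps = int(math.ceil(mc.horizon / dt))
    sqrt2dt = math.sqrt(2.0 * dt)
    for step in range(n_steps):
        t = (step + 1) * dt
        # activate newly entered ions
        newly = (~alive) & (~bound) & (entry_times <= t - dt)
        alive |= newly

        # scheduled unbinding
        rel = bound & (unbind_at <= t)
        if rel.any():
            idx = np.nonzero(rel)[0]
            log_event(idx, unbind_at[idx], EVENT_UNBIND)
            np.add.at(bound_count, trial_dense[idx], -1.0)
            bound[idx] = False
            alive[idx] = True
            unbind_at[idx] = np.inf
            # restart on the sensor surface (upper hemisphere)
            u = rng.standard_normal((len(idx), 3))
            u[:, 2] = np.abs(u[:, 2])
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pos[idx] = u * rho * (1.0 + 1e-9)
            state[idx] = 0

        act = np.nonzero(alive)[0]
        if len(act) == 0:
            continue

        # buffer switching; transitions are decided from the state at the
        # start of the step so capture and release are mutually exclusive
        if M:
            st0 = state[act].copy()
            free = act[st0 == 0]
            if len(free) and p_cap_tot > 0:
                u = rng.random(len(free))
                hit = u < p_cap_tot
                if hit.any():
                    chosen = rng.choice(M, size=int(hit.sum()), p=cap_weights) + 1
                    tgt = free[hit]
                    state[tgt] = chosen
                    if mc.record_buffer_events:
                        log_event(tgt, t, EVENT_CAPTURE)
            for i in range(1, M + 1):
                inb = act[st0 == i]
                if len(inb) and p_rel[i - 1] > 0:
                    u = rng.random(len(inb))
                    out = inb[u < p_rel[i - 1]]
                    if len(out):
                        state[out] = 0
                        if mc.record_buffer_events:
                            log_event(out, t, EVENT_RELEASE)

        # diffusion step
        if bridge:
            prev_pos = pos.copy()
        D = D_by_state[state[act]]
        moving = act[D > 0]
        if len(moving):
            sigma = np.sqrt(D[D > 0])[:, None] * sqrt2dt
            pos[moving] += sigma * rng.standard_normal((len(moving), 3))

        # reflections at plane and outer sphere
        pos[act] = _reflect(pos[act], rho, R)

        # sensor contact
        rr = np.linalg.norm(pos[act], axis=1)
        contact = act[rr < rho]
        if bridge:
            near = act[(rr >= rho) & (state[act] == 0)]
            if len(near):
                d_prev = np.linalg.norm(prev_pos[near], axis=1) - rho
                d_now = np.linalg.norm(pos[near], axis=1) - rho
                Dn = D_by_state[state[near]]
                with np.errstate(over="ignore", under="ignore"):
                    p_touch = np.exp(-d_prev * d_now / np.maximum(Dn * dt, 1e-300))
                touched = near[rng.random(len(near)) < p_touch]
                if len(touched):
                    # pull the touched walkers onto the surface so the
                    # ordinary contact branch below absorbs them
                    rr_t = np.linalg.norm(pos[touched], axis=1)
                    pos[touched] *= (rho * (1 - 1e-9) / rr_t)[:, None]
                    rr = np.linalg.norm(pos[act], axis=1)
                    contact = act[rr < rho]
        if len(contact):
            is_free = state[contact] == 0
            cand = contact[is_free]
            accept = np.zeros(len(cand), dtype=bool)
            if p_bind > 0 and len(cand):
                accept = rng.random(len(cand)) < p_bind
                if capacity != math.inf:
                    # enforce per-trial site capacity, first come first served
                    for k in np.nonzero(accept)[0]:
                        td = trial_dense[cand[k]]
                        if bound_count[td] >= capacity:
                            accept[k] = False
                        else:
                            bound_count[td] += 1.0
                else:
                    np.add.at(bound_count, trial_dense[cand[accept]], 1.0)
            newly_bound = cand[accept]
            if len(newly_bound):
                log_event(newly_bound, t, EVENT_BIND)
                bound[newly_bound] = True
                alive[newly_bound] = False
                if koff > 0:
                    unbind_at[newly_bound] = t + rng.exponential(1.0 / koff, len(newly_bound))
                pos[newly_bound] = 0.0
                pos[newly_bound, 2] = rho
            # reflect the rest radially off the sensor
            rejected = np.setdiff1d(contact, newly_bound, assume_unique=True)
            if len(rejected):
                rr_rej = np.linalg.norm(pos[rejected], axis=1)
                rr_rej = np.maximum(rr_rej, 1e-12)
                scale = (2.0 * rho - rr_rej) / rr_rej
                pos[rejected] *= scale[:, None]
                pos[rejected] = _reflect(pos[rejected], rho, R)
                rr_new = np.linalg.norm(pos[rejected], axis=1)
                bad = (rr_new > R * (1 + 1e-9)) | (rr_new < rho * (1 - 1e-6))
                if bad.any():
                    raise GeometryEscapeError(
                        f"{int(bad.sum())} particles outside the shell after reflection"
                    )

    order = None
    if ev_time:
        trial_arr = np.concatenate(ev_trial)
        ion_arr = np.concatenate(ev_ion)
        time_arr = np.concatenate(ev_time)
        code_arr = np.concatenate(ev_code)
        order = np.lexsort((time_arr, ion_arr, trial_arr))
        return EventLog(trial_arr[order], ion_arr[order], time_arr[order], code_arr[order],
                        n_trials=len(entries), horizon=mc.horizon)
    return EventLog(np.array([], dtype=int), np.array([], dtype=int), np.array([]),
                    np.array([], dtype=int), n_trials=len(entries), horizon=mc.horizon)


@dataclass(frozen=True)
class CountCurve:
    """Trial-averaged bound-count step function with across-trial SEM."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray | None

    def as_occupancy(self) -> OccupancyCurve:
        """Interpret the mean count as a probability (requires values <= 1)."""
        return OccupancyCurve(times=self.times, values=self.mean, provenance="mc", sem=self.sem)


def _per_trial_counts(log: EventLog, times: np.ndarray, statistic: str) -> np.ndarray:
    tr_b, _, t_b = log.select(EVENT_BIND)
    tr_u, _, t_u = log.select(EVENT_UNBIND)
    per_trial: dict = {}
    for tr, tt, sgn in ((tr_b, t_b, 1.0), (tr_u, t_u, -1.0)):
        for j, te in zip(tr, tt):
            per_trial.setdefault(int(j), []).append((float(te), sgn))
    counts = np.zeros((log.n_trials, len(times)))
    for row, evs in enumerate(per_trial.values()):
        evs.sort()
        te = np.array([e[0] for e in evs])
        cum = np.cumsum([e[1] for e in evs])
        idx = np.searchsorted(te, times, side="right") - 1
        vals = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        counts[row] = (vals > 0).astype(float) if statistic == "any_bound" else vals
    return counts


def estimate_occupancy(log: EventLog, times: np.ndarray, statistic: str = "mean_count") -> CountCurve:
    """Direct MC occupancy estimator from the event log.

    Per trial the bound count N_j(t) is a step function (+1 at binds,
    -1 at unbinds).  ``statistic="mean_count"`` averages N_j(t) over
    trials (the direct estimator of the expected number of bound ions);
    ``"any_bound"`` averages the indicator N_j(t) >= 1 (the direct
    estimator of the at-least-one-bound probability).  SEM is the
    across-trial standard error.
    """
    if statistic not in ("mean_count", "any_bound"):
        raise ValueError("statistic must be 'mean_count' or 'any_bound'")
    times = np.asarray(times, dtype=float)
    counts = _per_trial_counts(log, times, statistic)
    mean = counts.mean(axis=0)
    sem = counts.std(axis=0, ddof=1) / math.sqrt(log.n_trials) if log.n_trials > 1 else None
    return CountCurve(times=times, mean=mean, sem=sem)


def empirical_fpt(log: EventLog) -> dict:
    """Per-trial first-binding times with right-censoring.

    Returns ``{"times": sorted first-bind times, "n_censored": trials
    with no binding before the horizon, "horizon": horizon}``.
    """
    tr_b, _, t_b = log.select(EVENT_BIND)
    first = {}
    for j, te in zip(tr_b, t_b):
        if j not in first or te < first[j]:
            first[j] = te
    times = np.sort(np.array(list(first.values())))
    return {
        "times": times,
        "n_censored": log.n_trials - len(first),
        "horizon": log.horizon,
    }


def bound_intervals(log: EventLog) -> np.ndarray:
    """Durations of completed sensor-bound intervals (ms), across all ions."""
    df = log.to_frame()
    df = df[df["event"].isin(["bind", "unbind"])]
    out = []
    for (_, _), grp in df.groupby(["trial", "ion"]):
        seq = grp.sort_values("time_ms")
        tb = None
        for _, row in seq.iterrows():
            if row["event"] == "bind":
                tb = row["time_ms"]
            elif row["event"] == "unbind" and tb is not None:
                out.append(row["time_ms"] - tb)
                tb = None
    return np.asarray(out)
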