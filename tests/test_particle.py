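import numpy as np
import pytest

import calsensor as cs
from calsensor.particle import (
    EVENT_BIND,
    EVENT_CAPTURE,
    EVENT_RELEASE,
    MCConfig,
    bound_intervals,
    estimate_occupancy,
    single_ion_trials,
)


class TestSimulationBasics:
    def test_no_binding_produces_empty_log(self, ref_config):
        cfg = ref_config.with_sensor(k_on=0.0)
        mcc = MCConfig(dt=1e-4, horizon=0.05, n_trials=20, seed=1)
        log = cs.simulate_ions(cfg, mcc, single_ion_trials(20, cfg.geometry.r))
        assert len(log) == 0

    def test_empty_entries_give_empty_log(self, ref_config):
        mcc = MCConfig(dt=1e-4, horizon=0.01, n_trials=1, seed=1)
        log = cs.simulate_ions(cfg := ref_config, mcc,
                               cs.IonEntrySequence(times=np.array([])))
        assert len(log) == 0

    def test_too_large_step_rejected(self, ref_config):
        # binding acceptance probability exceeds 1
        with pytest.raises(ValueError, match="decrease dt"):
            mcc = MCConfig(dt=0.5, horizon=1.0, n_trials=1, seed=0)
            cs.simulate_ions(ref_config, mcc, single_ion_trials(1, 20.0))

    def test_step_warning_scales_with_geometry(self, ref_config):
        mcc = MCConfig(dt=1e-4, horizon=0.1, n_trials=1)
        assert mcc.step_warning(ref_config) is not None
        assert MCConfig(dt=5e-6, horizon=0.1, n_trials=1).step_warning(ref_config) is None

    def test_bind_unbind_alternate_per_ion(self, ref_config):
        mcc = MCConfig(dt=2e-5, horizon=0.4, n_trials=400, seed=11)
        log = cs.simulate_ions(ref_config, mcc, single_ion_trials(400, 20.0))
        df = log.to_frame()
        df = df[df["event"].isin(["bind", "unbind"])]
        for (_, _), grp in df.groupby(["trial", "ion"]):
            events = grp.sort_values("time_ms")["event"].tolist()
            assert events[::2] == ["bind"] * len(events[::2])
            assert events[1::2] == ["unbind"] * len(events[1::2])

    def test_seeded_runs_reproduce(self, ref_config):
        mcc = MCConfig(dt=5e-5, horizon=0.1, n_trials=50, seed=123)
        a = cs.simulate_ions(ref_config, mcc, single_ion_trials(50, 20.0))
        b = cs.simulate_ions(ref_config, mcc, single_ion_trials(50, 20.0))
        assert np.array_equal(a.time, b.time) and np.array_equal(a.event, b.event)


class TestEstimators:
    def test_no_events_give_zero_curve(self, ref_config):
        cfg = ref_config.with_sensor(k_on=0.0)
        mcc = MCConfig(dt=1e-4, horizon=0.02, n_trials=5, seed=2)
        log = cs.simulate_ions(cfg, mcc, single_ion_trials(5, 20.0))
        est = estimate_occupancy(log, np.array([0.005, 0.01]))
        assert np.all(est.mean == 0.0)

    def test_single_bind_is_indicator_step(self):
        from calsensor.particle import EventLog

        log = EventLog(
            trial=np.array([0]), ion=np.array([0]), time=np.array([0.5]),
            event=np.array([EVENT_BIND]), n_trials=1, horizon=2.0,
        )
        est = estimate_occupancy(log, np.array([0.1, 0.5, 1.5]))
        assert est.mean == pytest.approx([0.0, 1.0, 1.0])

    def test_estimator_statistics_modes(self, ref_config):
        mcc = MCConfig(dt=2e-5, horizon=0.15, n_trials=300, seed=9)
        log = cs.simulate_ions(ref_config, mcc, single_ion_trials(300, 20.0))
        t = np.array([0.01, 0.05, 0.1])
        mean_count = estimate_occupancy(log, t, statistic="mean_count")
        any_bound = estimate_occupancy(log, t, statistic="any_bound")
        # with one ion per trial both statistics coincide
        assert np.allclose(mean_count.mean, any_bound.mean)
        with pytest.raises(ValueError):
            estimate_occupancy(log, t, statistic="median")

    def test_first_passage_censoring_accounts_for_all_trials(self, ref_config):
        mcc = MCConfig(dt=2e-5, horizon=0.1, n_trials=200, seed=4)
        log = cs.simulate_ions(ref_config, mcc, single_ion_trials(200, 20.0))
        fpt = cs.empirical_fpt(log)
        assert len(fpt["times"]) + fpt["n_censored"] == 200
        assert np.all(fpt["times"] <= 0.1)


class TestPhysicalConsistency:
    def test_single_ion_occupancy_matches_analytic(self, ref_config):
        """Scaled-down MC validation: 3000 trials at dt = 20 ns against the
        residue-series curve, pointwise within 3 SEM."""
        n = 3000
        mcc = MCConfig(dt=2e-5, horizon=0.12, n_trials=n, seed=7)
        log = cs.simulate_ions(ref_config, mcc, single_ion_trials(n, 20.0))
        grid = np.logspace(-3, np.log10(0.12), 20)
        est = estimate_occupancy(log, grid)
        ana = cs.occupancy_single(ref_config, grid)
        z = np.abs(est.mean - ana.values) / np.where(est.sem > 0, est.sem, np.inf)
        assert np.nanmax(z) < 3.0

    def test_absorbing_limit_first_passage_distribution(self, ref_config):
        """Perfect absorber: the empirical first-passage CDF matches the
        analytic k_off=0, k_on=inf curve (KS over the simulated window)."""
        cfg = ref_config.with_sensor(k_on=float("inf"), k_off=0.0)
        n = 4000
        mcc = MCConfig(dt=1e-5, horizon=0.15, n_trials=n, seed=5)
        log = cs.simulate_ions(cfg, mcc, single_ion_trials(n, 20.0))
        fpt = cs.empirical_fpt(log)
        ts = np.linspace(5e-4, 0.15, 60)
        emp = np.searchsorted(fpt["times"], ts) / n
        ana = np.array([cs.invert_numeric(cfg, t) for t in ts])
        assert np.max(np.abs(emp - ana)) < 0.02

    def test_mean_bound_interval_matches_unbinding_rate(self, ref_config):
        """Average sensor-bound duration is 1/k_off ~ 0.064 ms."""
        n = 4000
        mcc = MCConfig(dt=2e-5, horizon=0.8, n_trials=n, seed=3)
        log = cs.simulate_ions(ref_config, mcc, single_ion_trials(n, 20.0))
        iv = bound_intervals(log)
        assert len(iv) > 50
        sem = np.std(iv, ddof=1) / np.sqrt(len(iv))
        assert abs(iv.mean() - 1.0 / 15.7) < 3 * sem + 0.002  # small censoring bias

    def test_buffer_occupancy_reaches_two_state_equilibrium(self, ref_config):
        """With no sensor, the fraction of time spent buffer-bound converges
        to k01/(k01 + k10)."""
        cfg = ref_config.with_sensor(k_on=0.0).with_buffers(
            [cs.reference_buffers()["EFB"]]
        )
        n, horizon, dt = 150, 3.0, 1e-4
        mcc = MCConfig(dt=dt, horizon=horizon, n_trials=n, seed=21,
                       record_buffer_events=True)
        log = cs.simulate_ions(cfg, mcc, single_ion_trials(n, 20.0))
        df = log.to_frame()
        fractions = []
        for j in range(n):
            sub = df[df["trial"] == j].sort_values("time_ms")
            bound_time, t_prev, in_buf = 0.0, 0.0, False
            for _, row in sub.iterrows():
                if in_buf:
                    bound_time += row["time_ms"] - t_prev
                t_prev = row["time_ms"]
                in_buf = row["event"] == "buffer_capture"
            if in_buf:
                bound_time += horizon - t_prev
            fractions.append(bound_time / horizon)
        fractions = np.array(fractions)
        expected = 400.0 / 410.0
        sem = fractions.std(ddof=1) / np.sqrt(n)
        assert abs(fractions.mean() - expected) < 3 * sem

    def test_unlimited_capacity_matches_independent_ion_formula(self, ref_config):
        """With unlimited capacity, N simultaneous ions per trial are exactly
        independent: the any-bound MC estimator agrees with the
        complement-power transform of the single-ion curve."""
        n_ions, n_trials = 10, 400
        entries = [
            cs.IonEntrySequence(times=np.zeros(n_ions), trial=j,
                                radii=np.full(n_ions, 20.0))
            for j in range(n_trials)
        ]
        mcc = MCConfig(dt=2e-5, horizon=0.08, n_trials=n_trials, seed=13)
        log = cs.simulate_ions(ref_config, mcc, entries)
        grid = np.logspace(-3, np.log10(0.08), 12)
        est = estimate_occupancy(log, grid, statistic="any_bound")
        ana = cs.occupancy_at_least_one(cs.occupancy_single(ref_config, grid), n_ions)
        z = np.abs(est.mean - ana.values) / np.where(est.sem > 0, est.sem, np.inf)
        assert np.nanmax(z) < 3.5

    def test_single_site_saturation_reduces_peak(self, ref_config):
        """A one-site sensor saturates: its occupancy stays below the
        unlimited-capacity prediction for many simultaneous ions."""
        n_ions, n_trials = 50, 150
        entries = [
            cs.IonEntrySequence(times=np.zeros(n_ions), trial=j,
                                radii=np.full(n_ions, 20.0))
            for j in range(n_trials)
        ]
        mcc = MCConfig(dt=2e-5, horizon=0.06, n_trials=n_trials, seed=17,
                       sensor_capacity=1)
        log = cs.simulate_ions(ref_config, mcc, entries)
        grid = np.logspace(-3, np.log10(0.06), 10)
        est = estimate_occupancy(log, grid, statistic="any_bound")
        ana = cs.occupancy_at_least_one(cs.occupancy_single(ref_config, grid), n_ions)
        assert np.max(est.mean) <= np.max(ana.values)
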