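import math

import numpy as np
import pytest

import calsensor as cs
from calsensor.influx import FWHM_TO_SIGMA, IonEntrySequence, mean_current, occupancy_trial


class TestGaussianFixture:
    def test_fwhm_sigma_identity(self):
        assert FWHM_TO_SIGMA == pytest.approx(2.3548, rel=1e-4)

    def test_reference_influx_statistics(self):
        seq = cs.gaussian_flux_fixture(200, fwhm=0.3, seed=42)
        assert len(seq) == 200
        assert np.all(np.diff(seq.times) >= 0)
        assert np.all(seq.times >= 0)
        sample_fwhm = FWHM_TO_SIGMA * np.std(seq.times, ddof=1)
        assert sample_fwhm == pytest.approx(0.3, rel=0.15)  # sampling error at N=200

    def test_seed_determinism(self):
        a = cs.gaussian_flux_fixture(50, seed=7)
        b = cs.gaussian_flux_fixture(50, seed=7)
        assert np.array_equal(a.times, b.times)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cs.gaussian_flux_fixture(0)
        with pytest.raises(ValueError):
            cs.gaussian_flux_fixture(10, fwhm=0.0)


class TestOccupancyTrial:
    def test_empty_sequence_gives_zero(self, ref_curve):
        seq = IonEntrySequence(times=np.array([]))
        assert np.all(occupancy_trial(seq, ref_curve).values == 0.0)

    def test_single_ion_at_zero_equals_single_curve(self, ref_curve):
        seq = IonEntrySequence(times=np.array([0.0]))
        out = occupancy_trial(seq, ref_curve)
        assert np.allclose(out.values, ref_curve.values, atol=1e-12)

    def test_simultaneous_ions_collapse_to_power_formula(self, ref_curve):
        n = 20
        seq = IonEntrySequence(times=np.zeros(n))
        out = occupancy_trial(seq, ref_curve)
        expected = cs.occupancy_at_least_one(ref_curve, n)
        assert np.allclose(out.values, expected.values, atol=1e-12)

    def test_entries_after_t_contribute_nothing(self, ref_curve):
        late = IonEntrySequence(times=np.array([ref_curve.times[-1] * 2]))
        assert np.all(occupancy_trial(late, ref_curve).values == 0.0)

    def test_shift_covariance(self, ref_config):
        """Delaying all entries by Delta shifts the trial curve by Delta."""
        t = np.linspace(0.005, 2.0, 400)
        p = cs.occupancy_single(ref_config, np.logspace(-4, 1, 300))
        seq = IonEntrySequence(times=np.array([0.0, 0.02, 0.05]))
        delta = 0.5
        base = occupancy_trial(seq, p, times=t)
        shifted = occupancy_trial(seq.shifted(delta), p, times=t)
        interp = np.interp(t - delta, t, base.values, left=0.0)
        mask = t - delta >= t[0]
        assert np.max(np.abs(shifted.values[mask] - interp[mask])) < 1e-9

    def test_bounded_by_simultaneous_release(self, ref_curve):
        # entries at a common time maximize overlap: pointwise,
        # P_trial(t) <= 1 - (1 - max_i P(t - t_i))^N
        seq = cs.gaussian_flux_fixture(50, fwhm=0.3, seed=1)
        out = occupancy_trial(seq, ref_curve)
        elapsed = out.times[:, None] - seq.times[None, :]
        pmax = np.max(np.where(elapsed > 0, ref_curve.interp(elapsed), 0.0), axis=1)
        bound = -np.expm1(50 * np.log1p(-pmax))
        assert np.all(out.values <= bound + 1e-12)


class TestOccupancyAP:
    def test_identical_trials_equal_single_trial(self, ref_curve):
        seq = IonEntrySequence(times=np.array([0.01, 0.02]))
        single = occupancy_trial(seq, ref_curve)
        avg = cs.occupancy_ap([seq, seq, seq], ref_curve)
        assert np.allclose(avg.values, single.values, atol=1e-15)

    def test_zero_ion_trials_scale_the_mean(self, ref_curve):
        seq = IonEntrySequence(times=np.array([0.01]))
        empty = IonEntrySequence(times=np.array([]))
        full = cs.occupancy_ap([seq], ref_curve)
        diluted = cs.occupancy_ap([seq, empty], ref_curve)
        assert np.allclose(diluted.values, 0.5 * full.values, atol=1e-15)

    def test_requires_at_least_one_trial(self, ref_curve):
        with pytest.raises(ValueError):
            cs.occupancy_ap([], ref_curve)


class TestGatingModel:
    def test_rates_positive_everywhere(self):
        m = cs.GatingModel()
        v = np.linspace(-120, 60, 50)
        assert np.all(m.alpha(v) > 0) and np.all(m.beta(v) > 0)

    def test_generator_rows_sum_to_zero(self):
        Q = cs.GatingModel().rate_matrix(-20.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_hyperpolarized_channel_stays_closed(self):
        m = cs.GatingModel()
        flat = lambda t: np.full_like(np.asarray(t, float), -120.0)
        assert cs.open_probability(m, flat) < 1e-3

    def test_channel_with_vanishing_rates_never_opens(self):
        m = cs.GatingModel(a0=1e-9, b0=1e-9)
        ap = cs.default_ap_waveform()
        _, _, entries = cs.simulate_channel(ap, m, dt=1e-3, seed=0)
        assert len(entries) == 0

    def test_current_conversion_constant(self):
        from calsensor.constants import IONS_PER_MS_PER_PA

        # 1 pA = 1e-12 C/s over charge 2e, scaled to ms
        assert IONS_PER_MS_PER_PA == pytest.approx(
            1e-12 / (2 * 1.602176634e-19) * 1e-3, rel=1e-12
        )

    def test_step_size_guard(self):
        with pytest.raises(ValueError):
            cs.simulate_channel(cs.default_ap_waveform(), cs.GatingModel(), dt=0.01)


@pytest.fixture(scope="module")
def calibrated():
    return cs.calibrate_gating()


class TestCalibration:

    def test_open_probability_target(self, calibrated):
        ap = cs.default_ap_waveform()
        assert cs.open_probability(calibrated, ap) == pytest.approx(0.3, abs=0.03)

    def test_current_characteristics(self, calibrated):
        ap = cs.default_ap_waveform()
        t = np.linspace(0, 2, 800)
        assert np.max(calibrated.i_open(ap(t))) == pytest.approx(0.3, rel=0.02)
        cur = mean_current(calibrated, ap, t)
        from calsensor.influx import _fwhm_of

        assert _fwhm_of(t, cur) == pytest.approx(0.25, rel=0.05)

    def test_stochastic_gating_consistent_with_master_equation(self, calibrated):
        ap = cs.default_ap_waveform()
        n = 1200
        opened = 0
        for j in range(n):
            o, _, _ = cs.simulate_channel(ap, calibrated, dt=1e-3, seed=99, trial=j)
            opened += bool(o.any())
        p_det = cs.open_probability(calibrated, ap)
        sem = math.sqrt(p_det * (1 - p_det) / n)
        assert abs(opened / n - p_det) < 4 * sem

    def test_entry_sequence_reproducible(self, calibrated):
        ap = cs.default_ap_waveform()
        _, _, a = cs.simulate_channel(ap, calibrated, dt=1e-3, seed=5, trial=3)
        _, _, b = cs.simulate_channel(ap, calibrated, dt=1e-3, seed=5, trial=3)
        assert np.array_equal(a.times, b.times)
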