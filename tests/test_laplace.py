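import numpy as np
import pytest
from scipy.integrate import solve_bvp

import calsensor as cs
from calsensor.laplace import (
    occupancy_laplace,
    occupancy_laplace_value,
    solve_survival,
    survival_free,
)


class TestSurvivalTrivial:
    def test_no_reaction_gives_survival_one(self, ref_config):
        cfg = ref_config.with_sensor(k_on=0.0)
        for p in (0.3, 2.0, 50.0):
            for r in (10.0, 100.0, 300.0):
                assert solve_survival(cfg, p, r).S0 == pytest.approx(1.0 / p, rel=1e-14)

    def test_binding_certain_in_bounded_domain(self, ref_config):
        # psi~_1(p -> 0+) -> 1: the first-passage density is normalized
        for r in (10.0, 20.0, 150.0):
            psi1 = 1.0 - 1e-10 * survival_free(1e-10, r, ref_config)
            assert psi1 == pytest.approx(1.0, abs=1e-5)

    def test_radius_outside_shell_rejected(self, ref_config):
        with pytest.raises(ValueError):
            solve_survival(ref_config, 1.0, 2.0)


class TestSurvivalAgainstBVP:
    def test_m0_matches_finite_difference_boundary_solve(self, ref_config):
        """Independent oracle: solve the radial Laplace-domain two-point
        boundary-value problem with scipy's collocation solver."""
        cfg = ref_config
        p, r_query = 1.0, 20.0
        D0, kappa = cfg.D0, cfg.kappa
        rho, R = cfg.geometry.rho, cfg.geometry.R

        def odes(r, y):
            # y = [S, S']; p S - 1 = D0 (S'' + 2/r S')
            return np.vstack([y[1], (p * y[0] - 1.0) / D0 - 2.0 * y[1] / r])

        def bc(ya, yb):
            return np.array([D0 * ya[1] - kappa * ya[0], yb[1]])

        mesh = np.linspace(rho, R, 4001)
        guess = np.vstack([np.full_like(mesh, 1.0 / p), np.zeros_like(mesh)])
        sol = solve_bvp(odes, bc, mesh, guess, tol=1e-12, max_nodes=200_000)
        assert sol.success
        oracle = float(sol.sol(r_query)[0])
        ours = survival_free(p, r_query, cfg).real
        assert ours == pytest.approx(oracle, rel=1e-8)

    def test_fixed_buffer_elimination_matches_scalar_oracle(self, efb_config):
        """Elimination of an immobile buffer gives a scalar modified-Helmholtz
        problem with a p-dependent effective rate; compare against an
        independently coded closed-form two-by-two solve."""
        cfg = efb_config
        b = cfg.buffers[0]
        rho, R, D0, kappa = cfg.geometry.rho, cfg.geometry.R, cfg.D0, cfg.kappa
        for p in (0.5, 7.0, 120.0):
            p_eff = p + b.binding_rate * p / (p + b.unbinding_rate)
            q = np.sqrt(p_eff / D0)
            # g = A e^{-q(r-rho)}/r + B e^{-q(R-r)}/r with Robin(rho), Neumann(R)
            e = np.exp(-q * (R - rho))

            def basis(r):
                f1, f2 = np.exp(-q * (r - rho)) / r, np.exp(-q * (R - r)) / r
                return f1, f2, (-q - 1 / r) * f1, (q - 1 / r) * f2

            _, _, f1pR, f2pR = basis(R)
            f1r, f2r, f1pr, f2pr = basis(rho)
            A = np.array(
                [
                    [f1pR, f2pR],
                    [D0 * f1pr - kappa * f1r, D0 * f2pr - kappa * f2r],
                ]
            )
            coef = np.linalg.solve(A, np.array([0.0, kappa / p]))
            for r in (10.0, 20.0, 120.0):
                f1, f2, _, _ = basis(r)
                oracle = coef[0] * f1 + coef[1] * f2 + 1.0 / p
                ours = survival_free(p, r, cfg).real
                assert ours == pytest.approx(oracle, rel=1e-10)

    def test_buffer_with_zero_binding_rate_equals_no_buffer(self, ref_config):
        dead = cs.BufferSpec("dead", D=0.1e6, k_on=100.0, c=0.0, k_off=10.0)
        cfg = ref_config.with_buffers([dead])
        for p in (0.5, 20.0):
            assert survival_free(p, 20.0, cfg).real == pytest.approx(
                survival_free(p, 20.0, ref_config).real, rel=1e-12
            )

    def test_buffer_states_returned_for_every_buffer(self, efb_config):
        out = solve_survival(efb_config, 3.0, 20.0)
        assert len(out.S_buffers) == 1
        # fixed-buffer elimination identity S~_1 = (1 + k10 S~_0)/(p + k10)
        b = efb_config.buffers[0]
        expected = (1.0 + b.unbinding_rate * out.S0) / (3.0 + b.unbinding_rate)
        assert out.S_buffers[0] == pytest.approx(expected, rel=1e-12)


class TestOccupancyLaplace:
    @pytest.mark.parametrize("p", [1e-3, 0.1, 1.0, 10.0, 1e3, 1e5])
    def test_laplace_occupancy_is_probability_bounded(self, ref_config, atp_config, p):
        for cfg in (ref_config, atp_config):
            val = (p * occupancy_laplace_value(cfg, p, 20.0)).real
            assert -1e-10 <= val <= 1.0 + 1e-10

    def test_no_unbinding_reduces_to_first_passage_cdf(self, ref_config):
        cfg = ref_config.with_sensor(k_off=0.0)
        for p in (0.5, 5.0):
            psi1 = 1.0 - p * survival_free(p, 20.0, cfg)
            assert occupancy_laplace_value(cfg, p, 20.0) == pytest.approx(psi1 / p)

    def test_no_binding_gives_zero(self, ref_config):
        cfg = ref_config.with_sensor(k_on=0.0)
        assert occupancy_laplace_value(cfg, 1.0, 20.0) == 0.0

    def test_small_p_limit_is_steady_state(self, ref_config):
        # p P~(p) -> P_inf + O(p); one Richardson step removes the O(p) term
        v = {p: (p * occupancy_laplace_value(ref_config, p, 20.0)).real
             for p in (2e-6, 1e-6)}
        extrapolated = 2 * v[1e-6] - v[2e-6]
        assert extrapolated == pytest.approx(cs.steady_state(ref_config), rel=1e-6)

    def test_record_carries_renewal_factors(self, ref_config):
        rec = occupancy_laplace(ref_config, 2.0)
        assert rec.r == ref_config.geometry.r
        koff = ref_config.sensor.k_off
        assert rec.P == pytest.approx(rec.psi1 / (2.0 + koff * (1.0 - rec.psi)))

    def test_depends_on_radius_only(self, ref_config):
        # the API admits no angular coordinates: occupancy is a function of
        # (p, r) alone, so two calls at the same radius must agree exactly
        a = occupancy_laplace_value(ref_config, 1.0, 37.5)
        b = occupancy_laplace_value(ref_config, 1.0, 37.5)
        assert a == b


class TestPropertyInvariants:
    """Randomized invariants of the Laplace-domain solution."""

    from hypothesis import given, settings, strategies as st

    @given(
        p=st.floats(min_value=1e-3, max_value=1e4),
        cd=st.floats(min_value=1.0, max_value=250.0),
        koff=st.floats(min_value=0.0, max_value=1e3),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scaled_occupancy_transform_is_probability(self, p, cd, koff):
        cfg = cs.default_config().with_geometry(r=5.0 + cd).with_sensor(k_off=koff)
        val = (p * occupancy_laplace_value(cfg, p, cfg.geometry.r)).real
        assert -1e-9 <= val <= 1.0 + 1e-9

    @given(
        p=st.floats(min_value=1e-2, max_value=1e3),
        c=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_buffering_never_accelerates_first_binding(self, p, c):
        # a buffer can only delay the first binding: S~_0 with buffer >= without
        buf = cs.BufferSpec("b", D=0.0, k_on=100.0, c=c, k_off=10.0)
        cfg0 = cs.default_config()
        cfg1 = cfg0.with_buffers([buf])
        s0 = survival_free(p, 20.0, cfg0).real
        s1 = survival_free(p, 20.0, cfg1).real
        assert s1 >= s0 - 1e-12
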