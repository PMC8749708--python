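"""Triplet kinetics, monomer-dimer equilibrium, and Stern-Volmer tests."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import palisim as ps
from palisim import constants as c


def ode_triplet(beta, n, alpha, t):
    """Independent oracle: stiff integration of the two-state pumping model
    dG/dt = -beta G + alpha T, dT/dt = beta G - alpha T."""
    if t == 0:
        return 0.0
    sol = solve_ivp(
        lambda _, y: [-beta * y[0] + alpha * y[1], beta * y[0] - alpha * y[1]],
        (0.0, t), [n, 0.0], method="Radau", rtol=1e-10, atol=1e-16 * n,
    )
    return sol.y[1, -1]


class TestTripletPopulation:
    def test_no_pumping_time(self):
        assert ps.triplet_population(1e6, 4e-4, 1e5, 0.0) == 0.0

    def test_saturation_limit(self):
        beta, alpha, n = 2e6, 1e6, 4e-4
        t = 1e3 / (alpha + beta)
        expected = beta * n / (alpha + beta)
        assert ps.triplet_population(beta, n, alpha, t) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_ode_oracle(self):
        beta = alpha = 1e6
        n, t = 4e-4, 1e-6
        got = ps.triplet_population(beta, n, alpha, t)
        assert got == pytest.approx(ode_triplet(beta, n, alpha, t), rel=1e-6)

    def test_zero_rates_limit(self):
        assert ps.triplet_population(0.0, 4e-4, 0.0, 1.0) == 0.0

    @given(
        beta=st.floats(1e3, 1e9), alpha=st.floats(1e2, 1e7),
        t=st.floats(1e-10, 1e-5),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_by_saturation(self, beta, alpha, t):
        n = 4e-4
        nt = ps.triplet_population(beta, n, alpha, t)
        assert 0 <= nt < n
        assert nt <= beta * n / (alpha + beta) * (1 + 1e-12)

    def test_monotone_in_time(self):
        ts = np.linspace(0, 1e-6, 50)
        vals = [ps.triplet_population(1e6, 4e-4, 2e5, t) for t in ts]
        assert np.all(np.diff(vals) > 0)


class TestPumpRate:
    def test_zero_fluence(self):
        assert ps.pump_rate(ps.PhotophysicalParams(), 0.0, 660.0) == 0.0

    def test_linearity(self):
        p = ps.PhotophysicalParams()
        assert ps.pump_rate(p, 2e6, 660.0) == pytest.approx(
            2 * ps.pump_rate(p, 1e6, 660.0), rel=1e-14
        )

    def test_dimensional_oracle(self):
        # hand computation: photon energy at 660 nm, then beta = eta sigma phi / (h nu)
        p = ps.PhotophysicalParams(eta=0.5, sigma_g=1e-16)
        h_nu = 6.62607015e-34 * 2.99792458e8 / 660e-9
        assert h_nu == pytest.approx(3.01e-19, rel=2e-3)
        expected = 0.5 * 1e-16 * 1e6 / h_nu
        assert ps.pump_rate(p, 1e6, 660.0) == pytest.approx(expected, rel=1e-12)


class TestSternVolmer:
    def test_zero_oxygen_gives_k0(self):
        cal = ps.SternVolmerCal(kQ=3.9e3, k0=1.84e4)
        assert ps.stern_volmer_rate(cal, 0.0) == cal.k0

    def test_monotone_in_pO2(self):
        cal = ps.SternVolmerCal()
        rates = ps.stern_volmer_rate(cal, np.linspace(0, 200, 30))
        assert np.all(np.diff(rates) > 0)

    def test_oxygenated_rate_from_flash_photolysis_constants(self):
        # kQ derived from the printed 150 / 0 mm Hg rates
        cal = ps.SternVolmerCal(kQ=3.91e3, k0=1.84e4)
        assert ps.stern_volmer_rate(cal, 150.0) == pytest.approx(6.05e5, rel=5e-3)

    def test_two_point_calibration_exact(self):
        kQ, k0 = 1234.5, 9876.0
        cal = ps.calibrate_stern_volmer([(0.0, k0), (150.0, k0 + 150 * kQ)])
        assert cal.kQ == pytest.approx(kQ, rel=1e-12)
        assert cal.k0 == pytest.approx(k0, rel=1e-12)

    def test_round_trip_noiseless(self):
        truth = ps.SternVolmerCal()
        pts = [(p, ps.stern_volmer_rate(truth, p)) for p in (0, 30, 60, 100, 150)]
        cal = ps.calibrate_stern_volmer(pts)
        for p in (0.0, 10.0, 42.0, 150.0):
            got, clamped = ps.invert_to_pO2(cal, ps.stern_volmer_rate(truth, p))
            assert not clamped
            assert got == pytest.approx(p, abs=1e-10 * max(p, 1))

    def test_noisy_matches_normal_equations(self):
        rng = np.random.default_rng(42)
        truth = ps.SternVolmerCal()
        pO2 = np.array([0.0, 40.0, 80.0, 120.0, 160.0])
        kt = ps.stern_volmer_rate(truth, pO2) + rng.normal(0, 1e3, 5)
        cal = ps.calibrate_stern_volmer(list(zip(pO2, kt)))
        # closed-form OLS oracle
        X = np.column_stack([pO2, np.ones(5)])
        beta = np.linalg.solve(X.T @ X, X.T @ kt)
        assert cal.kQ == pytest.approx(beta[0], rel=1e-10)
        assert cal.k0 == pytest.approx(beta[1], rel=1e-10)

    def test_degenerate_calibration(self):
        with pytest.raises(ValueError, match="degenerate"):
            ps.calibrate_stern_volmer([(50.0, 1e5), (50.0, 2e5)])

    def test_invert_clamps_below_k0(self):
        cal = ps.SternVolmerCal()
        got, clamped = ps.invert_to_pO2(cal, cal.k0 * 0.5)
        assert got == 0.0 and clamped

    def test_invert_at_k0_and_threshold_scale(self):
        cal = ps.SternVolmerCal()
        assert ps.invert_to_pO2(cal, cal.k0) == (0.0, False)
        got, _ = ps.invert_to_pO2(cal, cal.k0 + 10 * cal.kQ)
        assert got == pytest.approx(10.0, rel=1e-12)


class TestMonomerFraction:
    def test_no_dimerization(self):
        assert ps.monomer_fraction(4e-4, 0.0) == 1.0

    def test_half_monomer_at_400uM(self):
        # K = D / m^2 with m = 2e-4, D = 1e-4 gives K = 2500 1/M
        assert ps.monomer_fraction(4e-4, 2500.0) == pytest.approx(0.5, rel=1e-12)

    @given(total=st.floats(1e-6, 1e-2), k=st.floats(0.0, 1e6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mass_balance_residual(self, total, k):
        frac = ps.monomer_fraction(total, k)
        m = frac * total
        assert m + 2 * k * m * m == pytest.approx(total, rel=1e-10)

    def test_monotone_decreasing(self):
        ks = np.linspace(0, 1e5, 40)
        fr = [ps.monomer_fraction(4e-4, k) for k in ks]
        assert np.all(np.diff(fr) < 0)
        totals = np.linspace(1e-5, 1e-2, 40)
        fr2 = [ps.monomer_fraction(t, 2500.0) for t in totals]
        assert np.all(np.diff(fr2) < 0)


class TestTripletAbsorption:
    def test_zero_and_linearity(self):
        assert ps.triplet_absorption_coeff(0.0, 1e4) == 0.0
        one = ps.triplet_absorption_coeff(1e-4, 1e4)
        assert ps.triplet_absorption_coeff(3e-4, 1e4) == pytest.approx(
            3 * one, rel=1e-14
        )

    def test_decadic_conversion(self):
        assert ps.triplet_absorption_coeff(1e-4, 1e4) == pytest.approx(
            np.log(10.0), rel=1e-12
        )


class TestFlashPhotolysis:
    def test_no_triplet_flat_baseline(self):
        p = ps.PhotophysicalParams()
        tr = ps.simulate_flash_photolysis(p, 1e5, 1.0, 0.0, np.linspace(0, 1e-4, 20))
        assert np.allclose(tr, 1.0)

    def test_transmission_recovers(self):
        p = ps.PhotophysicalParams()
        tr = ps.simulate_flash_photolysis(
            p, 1e5, 1.0, 1e-5, np.linspace(0, 5e-5, 200)
        )
        assert tr[0] < tr[-1]
        assert np.all(np.diff(tr) > 0)

    def test_rate_recovery_through_fit(self):
        # -ln(T) decays as a clean exponential at the triplet rate
        p = ps.PhotophysicalParams()
        kt = 6.05e5
        times_us = np.asarray(ps.delay_schedule(12, 0.05, 20.0).delays_us)
        tr = ps.simulate_flash_photolysis(p, kt, 1.0, 1e-5, times_us * 1e-6)
        fit = ps.fit_decay(times_us, -np.log(tr), model="single")
        assert fit.selected_rate == pytest.approx(kt, rel=1e-3)
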