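"""Pressure generation, transducer projection, NEP, and SNR tests."""
import numpy as np
import pytest

import palisim as ps
from palisim.light_transport import FluenceMap


def make_fluence(values, voxel_mm=1.0):
    return FluenceMap(values=values, wavelength=830.0, n_photons=1,
                      seed=0, voxel_mm=voxel_mm)


def point_pressure_map(shape, idx, value, voxel_mm=1.0):
    vals = np.zeros(shape)
    vals[idx] = value
    return ps.PressureMap(values=vals, voxel_mm=voxel_mm)


class TestInitialPressure:
    def test_zero_absorber(self):
        fl = make_fluence(np.ones((4, 4, 4)))
        p = ps.initial_pressure(0.2, np.zeros((4, 4, 4)), fl)
        assert np.all(p.values == 0)

    def test_unit_conversion(self):
        # Gamma 0.2, mu_a 1 1/cm, phi 0.015 J/cm^2 -> 3e-3 J/cm^3 = 3 kPa
        fl = make_fluence(np.full((2, 2, 2), 0.015))
        p = ps.initial_pressure(0.2, np.ones((2, 2, 2)), fl)
        assert np.allclose(p.values, 3e-3)  # MPa

    def test_linearity_in_fluence(self):
        rng = np.random.default_rng(0)
        base = rng.random((3, 3, 3))
        mua = rng.random((3, 3, 3))
        p1 = ps.initial_pressure(0.2, mua, make_fluence(base))
        p2 = ps.initial_pressure(0.2, mua, make_fluence(2 * base))
        assert np.allclose(p2.values, 2 * p1.values)

    def test_grid_mismatch(self):
        fl = make_fluence(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="match"):
            ps.initial_pressure(0.2, np.ones((2, 2, 2)), fl)


class TestProjection:
    def test_focal_point_arrival_time(self):
        # single source at the focus, focal length 25 mm, sos 1540 m/s
        shape = (21, 21, 21)
        pm = point_pressure_map(shape, (10, 10, 10), 1.0)
        focus = ((10 + 0.5) * 1.0,) * 3
        xdcr = ps.TransducerSpec.focused_on(focus, focal_length_mm=25.0)
        tr = ps.project_to_transducer(pm, xdcr, sos=1540.0)
        t_peak = tr.times_us[np.argmax(np.abs(tr.samples))]
        assert t_peak == pytest.approx(25.0 / 1.54, abs=0.15)

    def test_superposition(self):
        shape = (15, 15, 15)
        xdcr = ps.TransducerSpec.focused_on((7.5, 7.5, 7.5))
        a = point_pressure_map(shape, (7, 7, 7), 1.0)
        b = point_pressure_map(shape, (8, 8, 8), 2.0)
        both = ps.PressureMap(values=a.values + b.values, voxel_mm=1.0)
        tr_a = ps.project_to_transducer(a, xdcr)
        tr_b = ps.project_to_transducer(b, xdcr)
        tr_ab = ps.project_to_transducer(both, xdcr)
        assert np.allclose(tr_ab.samples, tr_a.samples + tr_b.samples,
                           atol=1e-15)

    def test_superposition_random_maps(self):
        rng = np.random.default_rng(3)
        shape = (10, 10, 10)
        xdcr = ps.TransducerSpec.focused_on((5.0, 5.0, 5.0))
        m1 = ps.PressureMap(values=rng.random(shape), voxel_mm=1.0)
        m2 = ps.PressureMap(values=rng.random(shape), voxel_mm=1.0)
        msum = ps.PressureMap(values=m1.values + m2.values, voxel_mm=1.0)
        s = ps.project_to_transducer(msum, xdcr).samples
        s12 = (ps.project_to_transducer(m1, xdcr).samples
               + ps.project_to_transducer(m2, xdcr).samples)
        assert np.allclose(s, s12, atol=1e-12 * np.abs(s).max())

    def test_zero_map_zero_trace(self):
        pm = ps.PressureMap(values=np.zeros((5, 5, 5)), voxel_mm=1.0)
        xdcr = ps.TransducerSpec.focused_on((2.5, 2.5, 2.5))
        tr = ps.project_to_transducer(pm, xdcr)
        assert np.all(tr.samples == 0)

    def test_focus_outside_grid_flagged(self):
        pm = point_pressure_map((5, 5, 5), (2, 2, 2), 1.0)
        xdcr = ps.TransducerSpec(position_mm=(2.5, 2.5, -50.0),
                                 focal_length_mm=10.0)
        tr = ps.project_to_transducer(pm, xdcr)
        assert tr.focus_warning


class TestNoise:
    def test_zero_nep_identity(self):
        tr = ps.RFTrace(np.sin(np.linspace(0, 10, 100)))
        out = ps.add_noise(tr, ps.NoiseModel(nep=0.0, seed=1))
        assert np.array_equal(out.samples, tr.samples)

    def test_noise_std(self):
        tr = ps.RFTrace(np.zeros(10_000))
        out = ps.add_noise(tr, ps.NoiseModel(nep=0.5, seed=2))
        assert np.std(out.samples) == pytest.approx(0.5, rel=0.05)

    def test_seeded_determinism(self):
        tr = ps.RFTrace(np.zeros(256))
        a = ps.add_noise(tr, ps.NoiseModel(nep=1.0, seed=9))
        b = ps.add_noise(tr, ps.NoiseModel(nep=1.0, seed=9))
        assert np.array_equal(a.samples, b.samples)


def paired_traces(unoise, usig_pp, hsig_pp):
    """Constructed transducer/hydrophone pair: pre-arrival noise of exact
    RMS ``unoise``, then a square pulse of exact peak-to-peak amplitude."""
    n = 400
    u = np.zeros(n)
    h = np.zeros(n)
    u[:245] = unoise * (-1.0) ** np.arange(245)
    u[250:260] = usig_pp / 2.0
    u[260:270] = -usig_pp / 2.0
    h[250:260] = hsig_pp / 2.0
    h[260:270] = -hsig_pp / 2.0
    fs = 40.0
    window = (245 / fs, 280 / fs)
    return ps.RFTrace(u, fs), ps.RFTrace(h, fs), window


class TestComputeNep:
    def test_eq_arithmetic(self):
        u, h, w = paired_traces(2.0, 100.0, 50.0)
        assert ps.compute_nep(u, h, w) == pytest.approx(1.0, rel=1e-12)

    def test_unity_transfer(self):
        u, h, w = paired_traces(3.0, 80.0, 80.0)
        assert ps.compute_nep(u, h, w) == pytest.approx(3.0, rel=1e-12)

    def test_hydrophone_scaling(self):
        u, h, w = paired_traces(2.0, 100.0, 50.0)
        h10 = ps.RFTrace(h.samples * 10.0, h.sampling_rate_mhz)
        assert ps.compute_nep(u, h10, w) == pytest.approx(
            10.0 * ps.compute_nep(u, h, w), rel=1e-12
        )

    def test_no_signal_error(self):
        u, h, w = paired_traces(2.0, 100.0, 50.0)
        flat = ps.RFTrace(np.zeros_like(u.samples), u.sampling_rate_mhz)
        with pytest.raises(ValueError, match="detectable"):
            ps.compute_nep(flat, h, w)


class TestSnr:
    def test_amplitude_doubling(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, 400)
        sig = np.zeros(400)
        sig[300:320] = 5.0
        fs = 40.0
        t1 = ps.RFTrace(np.concatenate([noise, sig]), fs)
        t2 = ps.RFTrace(np.concatenate([noise, 2 * sig]), fs)
        w_sig = (400 / fs, 800 / fs)
        w_noise = (0.0, 399 / fs)
        assert ps.snr(t2, w_sig, w_noise) == pytest.approx(
            2 * ps.snr(t1, w_sig, w_noise), rel=1e-12
        )

    def test_silent_noise_window_infinite(self):
        samples = np.zeros(200)
        samples[150:160] = 1.0
        tr = ps.RFTrace(samples, 40.0)
        assert ps.snr(tr, (150 / 40, 160 / 40), (0.0, 100 / 40)) == np.inf

    def test_null_distribution_small(self):
        # pure noise in both windows: the estimator hovers near a small constant
        vals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            tr = ps.RFTrace(rng.normal(0, 1, 800), 40.0)
            vals.append(ps.snr(tr, (12.0, 19.9), (0.0, 10.0)))
        assert np.median(vals) < 3.0

    def test_overlapping_windows_rejected(self):
        tr = ps.RFTrace(np.ones(100), 40.0)
        with pytest.raises(ValueError, match="disjoint"):
            ps.snr(tr, (0.0, 1.0), (0.5, 1.5))


class TestNepInvariance:
    def test_joint_rescaling_invariance(self):
        # Eq-style ratio structure: scaling the transducer trace (signal
        # and noise together) leaves the NEP estimate unchanged
        u, h, w = paired_traces(2.0, 100.0, 50.0)
        u5 = ps.RFTrace(u.samples * 5.0, u.sampling_rate_mhz)
        assert ps.compute_nep(u5, h, w) == pytest.approx(
            ps.compute_nep(u, h, w), rel=1e-12
        )
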