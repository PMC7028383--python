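"""Excitation scaling, EAL fitting, cross-over depth and 3PE saturation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpcalcium import excitation as ex
from mpcalcium import synthetic_data as sd


def _train(energy_nj, tau_s=60e-15, rate=1e6):
    return ex.PulseTrain(
        rep_rate_hz=rate, pulse_duration_s=tau_s, pulse_energy_j=energy_nj * 1e-9
    )


class TestSignalScaling:
    def test_cubic_law(self):
        cal = ex.CalibrationConstants(c3=1e30)
        s1 = ex.signal_per_pulse(_train(1.0), cal, 3)
        s2 = ex.signal_per_pulse(_train(2.0), cal, 3)
        assert s2 / s1 == pytest.approx(8.0, rel=1e-12)

    def test_inverse_tau_law(self):
        cal = ex.CalibrationConstants(c2=1e10)
        s1 = ex.signal_per_pulse(_train(1.0, tau_s=120e-15), cal, 2)
        s2 = ex.signal_per_pulse(_train(1.0, tau_s=60e-15), cal, 2)
        assert s2 / s1 == pytest.approx(2.0, rel=1e-12)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            ex.signal_per_pulse(_train(1.0), ex.CalibrationConstants(), 4)

    @given(order=st.sampled_from([2, 3]), k=st.floats(1.1, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_loglog_slope_is_order(self, order, k):
        cal = ex.CalibrationConstants(c2=1e9, c3=1e28)
        s1 = ex.signal_per_pulse(_train(1.0), cal, order)
        s2 = ex.signal_per_pulse(_train(k), cal, order)
        assert math.log(s2 / s1) / math.log(k) == pytest.approx(order, rel=1e-9)


class TestCalibration:
    def test_single_point_exact(self):
        c3_true = 3.7e28
        e, tau = 1.5e-9, 60e-15
        s = c3_true * e**3 / tau**2
        cal = ex.calibrate_cn([(e, tau, s)], 3)
        assert cal.c3 == pytest.approx(c3_true, rel=1e-12)

    def test_noisy_points_recovery(self, rng):
        c3_true = 3.7e28
        rows = []
        for e in np.linspace(0.5e-9, 3e-9, 10):
            s = c3_true * e**3 / (60e-15) ** 2 * rng.lognormal(0, 0.05)
            rows.append((e, 60e-15, s))
        cal = ex.calibrate_cn(rows, 3)
        assert cal.c3 == pytest.approx(c3_true, rel=0.1)

    def test_roundtrip_prediction(self, rng):
        """Fit C3 on noisy synthetic data, predict signal within 10%."""
        c3_true = 5e27
        rows = [
            (e, 60e-15, c3_true * e**3 / (60e-15) ** 2 * rng.lognormal(0, 0.05))
            for e in np.linspace(1e-9, 2e-9, 8)
        ]
        cal = ex.calibrate_cn(rows, 3)
        pred = ex.signal_per_pulse(_train(1.5), cal, 3)
        truth = c3_true * (1.5e-9) ** 3 / (60e-15) ** 2
        assert pred == pytest.approx(truth, rel=0.1)

    def test_surface_normalisation(self):
        """The default generator coefficient yields 0.1 photon/pulse at z=0."""
        tab = sd.gen_depth_signal_table(293.0, 3, 1.86, np.arange(0, 700, 20))
        fit = ex.fit_eal(tab, 3)
        assert fit.surface_signal_per_pulse == pytest.approx(0.1, rel=1e-6)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            ex.calibrate_cn([(1e-9, 60e-15, 0.0)], 3)


class TestSurfacePulseEnergy:
    def test_two_eals(self):
        """1.86 nJ at the focus needs ~14 nJ at the surface from 2 EALs deep."""
        assert ex.surface_pulse_energy(1.86, 2 * 293.0, 293.0) == pytest.approx(
            14.0, rel=0.02
        )

    def test_four_eals(self):
        assert ex.surface_pulse_energy(1.86, 4 * 250.0, 250.0) == pytest.approx(
            100.0, rel=0.05
        )

    def test_zero_depth_identity(self):
        assert ex.surface_pulse_energy(1.23, 0.0, 300.0) == 1.23

    @given(a=st.floats(0, 500), b=st.floats(0, 500), e=st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_depth_semigroup(self, a, b, e):
        eal = 293.0
        direct = ex.surface_pulse_energy(e, a + b, eal)
        nested = ex.surface_pulse_energy(ex.surface_pulse_energy(e, a, eal), b, eal)
        assert direct == pytest.approx(nested, rel=1e-9)


class TestFitEAL:
    def test_noiseless_exact(self):
        tab = sd.gen_depth_signal_table(300.0, 3, 1.86, np.arange(0, 900, 30))
        fit = ex.fit_eal(tab, 3)
        assert fit.eal_um == pytest.approx(300.0, rel=1e-9)

    def test_noisy_recovery(self):
        tab = sd.gen_depth_signal_table(
            300.0, 3, 1.86, np.linspace(0, 1000, 50), noise_cv=0.05, seed=5
        )
        fit = ex.fit_eal(tab, 3)
        assert fit.eal_um == pytest.approx(300.0, rel=0.05)

    def test_focus_power_fraction_decades(self):
        """At z = n·ln10·EAL the focus-power fraction has dropped 10^−n... in
        signal, i.e. the power fraction is 10^−n per the nth-root convention."""
        eal, order = 250.0, 2
        z = np.array([0.0, eal * order * math.log(10.0) / 2, eal * order * math.log(10.0)])
        tab = sd.gen_depth_signal_table(eal, order, 0.24, np.linspace(0, z[-1], 30))
        fit = ex.fit_eal(tab, order)
        frac_at = np.interp(z[-1], fit.depth_um, fit.focus_power_fraction)
        assert frac_at == pytest.approx(10.0 ** (-order), rel=1e-3)

    def test_non_monotone_rejected(self):
        tab = sd.gen_depth_signal_table(300.0, 3, 1.86, [0, 50, 40])
        with pytest.raises(ValueError):
            ex.fit_eal(tab, 3)


class TestCrossover:
    def test_printed_inputs(self):
        """GCaMP6s surface energies and measured EALs give ~646 μm."""
        z = ex.crossover_depth(0.24, 1.86, 153.0, 297.0)
        assert z == pytest.approx(646.0, abs=5.0)

    def test_equal_energies(self):
        assert ex.crossover_depth(1.0, 1.0, 153.0, 297.0) == 0.0

    def test_unit_invariance(self):
        z1 = ex.crossover_depth(0.24, 1.86, 153.0, 297.0)
        z2 = ex.crossover_depth(240.0, 1860.0, 153.0, 297.0)
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_no_crossover_signalled(self):
        with pytest.raises(ValueError):
            ex.crossover_depth(1.86, 0.24, 153.0, 297.0)


class TestSaturation:
    def test_printed_energies(self):
        """GCaMP6s 3PE: 10%/63% excitation at ~2 and ~4.3 nJ."""
        p = ex.SaturationParams()
        assert ex.saturation_probability(4.3, p) == pytest.approx(0.63, rel=0.15)
        assert ex.saturation_probability(2.0, p) == pytest.approx(0.10, rel=0.15)

    def test_inverse(self):
        p = ex.SaturationParams()
        e63 = ex.saturation_energy(1.0 - 1.0 / math.e, p)
        assert e63 == pytest.approx(4.3, rel=0.15)
        assert ex.saturation_probability(e63, p) == pytest.approx(1 - 1 / math.e, rel=1e-9)

    def test_cube_law_consistency(self):
        """Energies for exponents 1 and 0.105 differ by (1/0.105)^(1/3) exactly."""
        p = ex.SaturationParams()
        r = ex.saturation_energy(1.0 - math.exp(-1.0), p) / ex.saturation_energy(
            1.0 - math.exp(-0.105), p
        )
        assert r == pytest.approx((1.0 / 0.105) ** (1.0 / 3.0), rel=1e-9)
        assert r == pytest.approx(4.3 / 2.0, rel=0.02)

    def test_monotone_and_zero_limit(self):
        p = ex.SaturationParams()
        es = np.linspace(0.1, 10, 50)
        prs = [ex.saturation_probability(e, p) for e in es]
        assert np.all(np.diff(prs) > 0)
        assert ex.saturation_probability(1e-4, p) < 1e-9
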