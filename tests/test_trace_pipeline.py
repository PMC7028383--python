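"""Trace measurements: conversion, normalisation, spike inference, ratios."""

import numpy as np
import pytest

from mpcalcium import fidelity as fi
from mpcalcium import synthetic_data as sd
from mpcalcium import trace_pipeline as tp
from mpcalcium.fidelity import GCAMP6S, IndicatorParams


class TestPhotonConversion:
    def test_zero_image(self):
        img = np.full((16, 16), 100.0)
        assert np.all(tp.pixels_to_photons(img, 40.0, offset=100.0) == 0.0)

    def test_calibration_recovery(self):
        img, _ = sd.gen_photon_image(conversion_factor=40.0, offset=100.0, seed=3)
        factor, offset = tp.estimate_conversion_factor(img)
        assert factor == pytest.approx(40.0, rel=0.05)
        assert offset == pytest.approx(100.0, abs=2.0)

    def test_linearity_in_photon_rate(self, rng):
        """Doubling the photon rate doubles converted counts within shot noise."""
        img1, _ = sd.gen_photon_image(mean_photons=0.5, seed=10)
        img2, _ = sd.gen_photon_image(mean_photons=1.0, seed=11)
        c1 = tp.pixels_to_photons(img1, 40.0, 100.0).sum()
        c2 = tp.pixels_to_photons(img2, 40.0, 100.0).sum()
        assert c2 / c1 == pytest.approx(2.0, rel=0.05)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            tp.pixels_to_photons(np.zeros((4, 4)), 0.0)


class TestPreprocess:
    def test_constant_trace_normalises_to_zero(self):
        rec = tp.TraceRecording(frame_rate_hz=13.6, photons=np.full(500, 80.0))
        dff, f0 = tp.preprocess(rec)
        assert np.allclose(dff, 0.0, atol=1e-12)
        assert f0 == pytest.approx(80.0)

    def test_recovers_transient_amplitude(self):
        """ΔF/F = 0.3 transients at a generous photon budget come back 0.30±0.02."""
        spec = sd.TraceSpec(
            f0_photons_per_s=20000.0, spike_times_s=(15.0, 45.0), seed=6
        )
        rec, _ = sd.gen_trace(spec)
        dff, _ = tp.preprocess(rec)
        assert dff.max() == pytest.approx(0.30, abs=0.02)

    def test_filter_preserves_dc(self, rng):
        x = rng.poisson(50.0, size=800).astype(float)
        sm = tp._smooth(x, 13.6, 0.37)
        assert sm[20:-20].mean() == pytest.approx(x[20:-20].mean(), rel=1e-3)

    def test_short_trace_rejected(self):
        rec = tp.TraceRecording(frame_rate_hz=13.6, photons=np.ones(3))
        with pytest.raises(ValueError):
            tp.preprocess(rec)


class TestInferSpikes:
    def test_clean_transients_found_at_onsets(self):
        """At a very high photon budget the three transients are found at
        their true onsets within one frame."""
        fr = 13.6
        spec = sd.TraceSpec(
            f0_photons_per_s=2e5, spike_times_s=(10.0, 30.0, 50.0),
            frame_rate_hz=fr, seed=4,
        )
        rec, truth = sd.gen_trace(spec)
        events = tp.infer_spikes(rec)
        assert len(events) == 3
        onsets = np.array([e.onset_index for e in events]) / fr
        assert np.allclose(onsets, truth, atol=1.5 / fr)

    def test_operating_point_at_dprime_three(self, rng):
        """Matched-filter detection at F0 = 100 photons/s (d' = 3) reproduces
        the ~93%/7% true/false-positive rates."""
        fr = 13.6
        f0 = fi.min_baseline_rate(GCAMP6S, 3.0)
        lam = f0 / fr
        a = GCAMP6S.dff_single_ap * np.exp(
            -np.arange(int(3 * GCAMP6S.tau_decay_s * fr)) / (GCAMP6S.tau_decay_s * fr)
        )
        mu0, mu1, _ = tp.llr_stat_moments(lam, GCAMP6S, fr)
        thr = 0.5 * (mu0 + mu1)
        n = 2000
        w = np.log1p(a)
        x0 = rng.poisson(lam, size=(n, a.size))
        x1 = rng.poisson(lam * (1.0 + a), size=(n, a.size))
        det = lam * a.sum()
        tpr = ((x1 @ w - det) > thr).mean()
        fpr = ((x0 @ w - det) > thr).mean()
        assert tpr == pytest.approx(0.93, abs=0.03)
        assert fpr == pytest.approx(0.07, abs=0.03)

    def test_detection_monotone_in_photon_rate(self, rng):
        fr = 13.6
        a = GCAMP6S.dff_single_ap * np.exp(
            -np.arange(int(3 * GCAMP6S.tau_decay_s * fr)) / (GCAMP6S.tau_decay_s * fr)
        )
        w = np.log1p(a)
        rates = []
        for f0 in (25.0, 100.0, 400.0):
            lam = f0 / fr
            mu0, mu1, _ = tp.llr_stat_moments(lam, GCAMP6S, fr)
            thr = 0.5 * (mu0 + mu1)
            x1 = rng.poisson(lam * (1.0 + a), size=(1500, a.size))
            rates.append(((x1 @ w - lam * a.sum()) > thr).mean())
        assert rates[0] < rates[1] < rates[2]

    def test_llr_consistent_with_fidelity_dprime(self):
        """The matched-filter separation (μ1−μ0)/σ0 approaches the analytic
        shot-noise d' for small ΔF/F."""
        fr = 50.0
        ind = IndicatorParams(0.05, 2.0)
        f0 = 4000.0
        mu0, mu1, sd0 = tp.llr_stat_moments(f0 / fr, ind, fr)
        analytic = fi.dprime(ind, f0)
        assert (mu1 - mu0) / sd0 == pytest.approx(analytic, rel=0.03)


class TestDffRatio:
    def _burst(self):  # 3-AP bursts: ΔF/F 0.9, comfortably above the 0.3 peak cut
        return IndicatorParams(0.9, 2.0)

    def test_identical_channels_unity(self):
        spec = sd.TraceSpec(
            indicator=self._burst(), f0_photons_per_s=20000.0,
            spike_times_s=(10.0, 30.0, 50.0), seed=2,
        )
        r3, _ = sd.gen_trace(spec)
        res = tp.dff_ratio(r3, r3)
        assert res.ratios == pytest.approx(np.ones(len(res.ratios)), abs=1e-9)
        assert res.pearson_r == pytest.approx(1.0)

    def test_background_halves_ratio(self):
        """A 2P channel with background B = F0 (SBR = 1) shows half the ΔF/F."""
        ind = self._burst()
        s3 = sd.TraceSpec(
            indicator=ind, f0_photons_per_s=20000.0,
            spike_times_s=(10.0, 30.0, 50.0), seed=7,
        )
        s2 = sd.TraceSpec(
            indicator=ind, f0_photons_per_s=20000.0,
            background_photons_per_s=20000.0,
            spike_times_s=(10.0, 30.0, 50.0), seed=8,
        )
        r3, r2, _ = sd.gen_paired_traces(s3, s2)
        res = tp.dff_ratio(r3, r2)
        assert len(res.ratios) == 3
        assert res.ratios.mean() == pytest.approx(0.5, abs=0.07)

    def test_noisy_background_free_pair_near_unity(self):
        """Shot noise alone leaves the per-transient ratio within 1.0 ± 0.25."""
        ind = self._burst()
        s3 = sd.TraceSpec(
            indicator=ind, f0_photons_per_s=800.0,
            spike_times_s=tuple(np.arange(8.0, 72.0, 8.0)), seed=21,
        )
        s2 = sd.TraceSpec(indicator=ind, f0_photons_per_s=800.0, seed=22)
        r3, r2, _ = sd.gen_paired_traces(s3, s2)
        res = tp.dff_ratio(r3, r2)
        assert len(res.ratios) >= 5
        assert abs(res.ratios.mean() - 1.0) < 0.25

    def test_gain_invariance(self):
        ind = self._burst()
        spec = sd.TraceSpec(
            indicator=ind, f0_photons_per_s=20000.0,
            spike_times_s=(10.0, 30.0, 50.0), seed=9,
        )
        r3, _ = sd.gen_trace(spec)
        scaled3 = tp.TraceRecording(r3.frame_rate_hz, r3.photons * 3.0)
        scaled2 = tp.TraceRecording(r3.frame_rate_hz, r3.photons * 3.0)
        base = tp.dff_ratio(r3, r3)
        scaled = tp.dff_ratio(scaled3, scaled2)
        assert scaled.ratios == pytest.approx(base.ratios, rel=1e-9)

    def test_mismatched_traces_rejected(self):
        a = tp.TraceRecording(13.6, np.ones(100))
        b = tp.TraceRecording(13.6, np.ones(80))
        with pytest.raises(ValueError):
            tp.dff_ratio(a, b)
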