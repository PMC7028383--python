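"""Monte Carlo transport: launch statistics, analytic limits, conservation."""

import math

import numpy as np
import pytest
from scipy import stats

from mpcalcium import mc_transport as mt


def _pencil_states(n, x=0.0):
    """Collimated pencil beam straight down from the surface."""
    return (
        np.full(n, x), np.zeros(n), np.full(n, 1e-9),
        np.zeros(n), np.zeros(n), np.ones(n),
    )


class TestLaunch:
    def test_axial_ray(self, beam_1mm):
        pos, d = mt.launch_photon(beam_1mm, u=1.0)
        assert pos[0] == pytest.approx(0.0)
        assert d[2] == pytest.approx(1.0)

    def test_gaussian_back_aperture(self, beam_1mm, rng):
        """Radial offsets at the back aperture follow the 1/e² Gaussian-beam
        (Rayleigh) distribution with scale w0/2."""
        u = 1.0 - rng.random(100_000)
        w = beam_1mm.w0_mm * np.sqrt(-np.log(u) / 2.0)
        ks = stats.kstest(w, stats.rayleigh(scale=beam_1mm.w0_mm / 2.0).cdf)
        assert ks.pvalue > 0.01

    def test_effective_na(self, beam_1mm):
        """The 1/e² marginal ray corresponds to an effective NA of ~0.75."""
        u_at_w0 = math.exp(-2.0)  # draw that maps exactly to w = w0
        _, d = mt.launch_photon(beam_1mm, u=u_at_w0)
        sin_theta = math.sqrt(d[0] ** 2 + d[1] ** 2)
        assert beam_1mm.n0 * sin_theta == pytest.approx(0.75, abs=0.05)

    def test_rays_converge_on_focus(self, beam_1mm, rng):
        states = mt.launch_batch(beam_1mm, 2000, rng)
        x, y, z, ux, uy, uz = states
        zf = beam_1mm.z_focus_um * 1e-3
        t = zf / uz
        xf = x + ux * t
        yf = y + uy * t
        r_focus = np.sqrt(xf**2 + yf**2)
        assert r_focus.max() <= 0.5 * beam_1mm.fov_diameter_um * 1e-3 + 1e-9

    def test_over_aperture_rejected(self, beam_1mm):
        with pytest.raises(ValueError):
            mt.launch_photon(beam_1mm, u=1e-300)


class TestPropagate:
    def test_beer_lambert_limit(self):
        """Without scattering the depth-resolved absorption is exponential."""
        tissue = mt.TissueOpticalParams(mua_per_mm=1.0, mus_per_mm=0.0, g=0.0)
        geom = mt.SimulationGeometry(voxel_um=100.0)
        grid = mt.propagate(_pencil_states(200_000), geom, tissue, seed=3)
        dz = grid.z_edges_mm[1] - grid.z_edges_mm[0]
        profile = grid.values[:, 0]  # all deposits on the axis column
        vol = np.pi * grid.r_edges_mm[1] ** 2 * dz
        absorbed = profile * vol  # fraction per bin
        z0 = grid.z_edges_mm[:-1]
        expected = np.exp(-z0) - np.exp(-(z0 + dz))
        sel = expected > 1e-4
        assert np.allclose(absorbed[sel], expected[sel], rtol=0.05, atol=2e-4)

    def test_weight_conservation(self, absorption_1320):
        total = sum(absorption_1320.fate_summary.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_volume_integral_matches_heating(self, absorption_1320):
        r = absorption_1320.r_edges_mm
        dz = absorption_1320.z_edges_mm[1] - absorption_1320.z_edges_mm[0]
        vol = (np.pi * (r[1:] ** 2 - r[:-1] ** 2))[None, :] * dz
        assert (absorption_1320.values * vol).sum() == pytest.approx(
            absorption_1320.fate_summary["heating"], rel=1e-9
        )

    def test_analog_oracle_thin_slab(self, rng):
        """Weighted transport matches an unweighted (analog) simulation."""
        mua, mus, g, thick = 1.0, 2.0, 0.5, 0.3
        tissue = mt.TissueOpticalParams(mua_per_mm=mua, mus_per_mm=mus, g=g)
        geom = mt.SimulationGeometry(
            escape_radius_mm=50.0, escape_depth_mm=thick, voxel_um=100.0,
            window_radius_mm=50.0,
        )
        n = 100_000
        res = mt.propagate(_pencil_states(n), geom, tissue, seed=9)

        # analog MC: photons absorbed or scattered event by event
        n2 = 100_000
        absorbed = back = through = 0
        mut = mua + mus
        for _ in range(n2):
            z = 0.0
            uz = 1.0
            ux = uy = 0.0
            while True:
                step = -math.log(1.0 - rng.random()) / mut
                z += uz * step
                if z < 0:
                    back += 1
                    break
                if z > thick:
                    through += 1
                    break
                if rng.random() < mua / mut:
                    absorbed += 1
                    break
                # HG scatter
                tmp = (1 - g * g) / (1 - g + 2 * g * rng.random())
                cost = (1 + g * g - tmp * tmp) / (2 * g)
                sint = math.sqrt(max(0.0, 1 - cost * cost))
                psi = 2 * math.pi * rng.random()
                if abs(uz) > 0.99999:
                    ux, uy, uz = sint * math.cos(psi), sint * math.sin(psi), (cost if uz > 0 else -cost)
                else:
                    den = math.sqrt(1 - uz * uz)
                    ux, uy, uz = (
                        sint * (ux * uz * math.cos(psi) - uy * math.sin(psi)) / den + ux * cost,
                        sint * (uy * uz * math.cos(psi) + ux * math.sin(psi)) / den + uy * cost,
                        -sint * math.cos(psi) * den + uz * cost,
                    )
        for key, count in [("heating", absorbed), ("window", back), ("escaped", through)]:
            p = count / n2
            sigma = math.sqrt(p * (1 - p) * (1 / n + 1 / n2))
            assert abs(res.fate_summary[key] - p) < 3.5 * sigma, key

    def test_nan_weights_rejected(self, geom_default):
        tissue = mt.tissue_for_wavelength(1320)
        states = _pencil_states(10)
        with pytest.raises(ValueError):
            mt.propagate(states, geom_default, tissue, seed=1, weights=np.full(10, np.nan))


class TestSimulate:
    def test_seed_reproducibility(self, beam_1mm, geom_default):
        tissue = mt.tissue_for_wavelength(1320)
        a = mt.simulate(beam_1mm, geom_default, tissue, n_photons=20_000, seed=7)
        b = mt.simulate(beam_1mm, geom_default, tissue, n_photons=20_000, seed=7)
        assert np.array_equal(a.values, b.values)
        assert a.fate_summary == b.fate_summary

    def test_seed_independence_within_error(self, beam_1mm, geom_default):
        tissue = mt.tissue_for_wavelength(1320)
        a = mt.simulate(beam_1mm, geom_default, tissue, n_photons=40_000, seed=1)
        b = mt.simulate(beam_1mm, geom_default, tissue, n_photons=40_000, seed=2)
        diff = abs(a.fate_summary["heating"] - b.fate_summary["heating"])
        sigma = math.sqrt(a.fate_stderr["heating"] ** 2 + b.fate_stderr["heating"] ** 2)
        assert diff < 4 * sigma

    def test_heating_monotone_in_absorption(self, beam_1mm, geom_default):
        fracs = []
        for mua in (0.04, 0.12, 0.3):
            tissue = mt.TissueOpticalParams(mua_per_mm=mua, mus_per_mm=3.2)
            g = mt.simulate(beam_1mm, geom_default, tissue, n_photons=30_000, seed=4)
            fracs.append(g.fate_summary["heating"])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_transparent_medium_escapes(self, beam_1mm, geom_default):
        tissue = mt.TissueOpticalParams(mua_per_mm=0.0, mus_per_mm=0.0)
        g = mt.simulate(beam_1mm, geom_default, tissue, n_photons=5_000, seed=8)
        assert g.fate_summary["escaped"] == pytest.approx(1.0)
        assert g.fate_summary["heating"] == 0.0
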