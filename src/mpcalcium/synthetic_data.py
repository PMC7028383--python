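"""Generators emulating the study's raw data.

Every measurement stage of the package is exercised end to end on synthetic
inputs whose ground truth is known by construction:

* shot-noise-limited calcium traces — Poisson photon counts around a baseline
  rate F0 modulated by exponential-decay transients (GCaMP6s defaults:
  ΔF/F 30%, τ 2 s) plus an optional constant background;
* depth stacks of vessel-like structures — random cylinders at ~2% volume
  fraction (staining inhomogeneity χ ≈ 50), per-plane signal attenuated as
  exp(−n·z/EAL) and a background floor imposed from the theoretical SBR(z);
* depth-resolved signal tables following the n-photon power law, for
  attenuation-length fitting;
* pixel-value images with a known photon conversion factor and offset.

All generators are driven by an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fidelity import GCAMP6S, IndicatorParams
from .sbr_model import StainingModel, sbr_vs_depth
from .trace_pipeline import TraceRecording

__all__ = [
    "TraceSpec",
    "StackSpec",
    "gen_trace",
    "gen_paired_traces",
    "gen_stack",
    "gen_depth_signal_table",
    "gen_photon_image",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a synthetic shot-noise-limited calcium trace."""

    indicator: IndicatorParams = GCAMP6S
    f0_photons_per_s: float = 100.0
    background_photons_per_s: float = 0.0
    frame_rate_hz: float = 13.6
    duration_s: float = 75.0
    spike_times_s: tuple[float, ...] | None = None
    poisson_rate_hz: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_photons_per_s < 0 or self.background_photons_per_s < 0:
            raise ValueError("rates must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration must be > 0")


def _rate_curve(spec: TraceSpec, spikes: np.ndarray) -> np.ndarray:
    """Expected photon rate per frame (photons/frame)."""
    n = int(round(spec.duration_s * spec.frame_rate_hz))
    t = (np.arange(n) + 0.5) / spec.frame_rate_hz
    dff = np.zeros(n)
    ind = spec.indicator
    for tk in spikes:
        on = t >= tk
        dff[on] += ind.dff_single_ap * np.exp(-(t[on] - tk) / ind.tau_decay_s)
    rate = spec.f0_photons_per_s * (1.0 + dff) + spec.background_photons_per_s
    return rate / spec.frame_rate_hz


def gen_trace(spec: TraceSpec) -> tuple[TraceRecording, np.ndarray]:
    """Generate one trace; returns (recording, ground-truth spike times)."""
    rng = np.random.default_rng(spec.seed)
    if spec.spike_times_s is not None:
        spikes = np.asarray(spec.spike_times_s, dtype=float)
    elif spec.poisson_rate_hz > 0:
        n_exp = spec.poisson_rate_hz * spec.duration_s
        k = rng.poisson(n_exp)
        spikes = np.sort(rng.uniform(0.0, spec.duration_s, size=k))
    else:
        spikes = np.empty(0)
    lam = _rate_curve(spec, spikes)
    photons = rng.poisson(lam).astype(float)
    rec = TraceRecording(frame_rate_hz=spec.frame_rate_hz, photons=photons)
    return rec, spikes


def gen_paired_traces(
    spec3p: TraceSpec, spec2p: TraceSpec
) -> tuple[TraceRecording, TraceRecording, np.ndarray]:
    """Simultaneous two-channel recordings sharing one spike train.

    The 3P spec's spike train (explicit or Poisson-drawn) drives both
    channels; channel-specific baselines/backgrounds and independent photon
    noise come from each spec.
    """
    rng = np.random.default_rng(spec3p.seed)
    if spec3p.spike_times_s is not None:
        spikes = np.asarray(spec3p.spike_times_s, dtype=float)
    else:
        k = rng.poisson(spec3p.poisson_rate_hz * spec3p.duration_s)
        spikes = np.sort(rng.uniform(0.0, spec3p.duration_s, size=k))
    rec3 = TraceRecording(
        frame_rate_hz=spec3p.frame_rate_hz,
        photons=rng.poisson(_rate_curve(spec3p, spikes)).astype(float),
        channel="3P",
    )
    rec2 = TraceRecording(
        frame_rate_hz=spec2p.frame_rate_hz,
        photons=rng.poisson(_rate_curve(spec2p, spikes)).astype(float),
        channel="2P",
    )
    return rec3, rec2, spikes


@dataclass(frozen=True)
class StackSpec:
    """Parameters of a synthetic vasculature depth stack."""

    nz: int = 12
    ny: int = 128
    nx: int = 128
    voxel_um: float = 2.0
    vessel_volume_fraction: float = 0.02
    vessel_diameter_um: float = 8.0
    eal_um: float = 154.0
    order: int = 2
    chi: float = 50.0
    surface_signal: float = 5000.0
    depth_step_um: float = 30.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.vessel_volume_fraction < 1.0:
            raise ValueError("vessel_volume_fraction must be in (0, 1)")
        if not self.vessel_diameter_um > 0:
            raise ValueError("vessel_diameter_um must be > 0")
        if self.vessel_diameter_um >= 20.0:
            raise ValueError("vessels are capillaries/venules: diameter < 20 μm")


def _draw_vessels(spec: StackSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary vessel mask from random straight cylinders at the target fraction."""
    shape = (spec.nz, spec.ny, spec.nx)
    mask = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.meshgrid(
        np.arange(spec.nz), np.arange(spec.ny), np.arange(spec.nx), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float) * spec.voxel_um
    radius = spec.vessel_diameter_um / 2.0
    target = spec.vessel_volume_fraction
    extent = np.array([spec.nz, spec.ny, spec.nx]) * spec.voxel_um
    rejected = 0
    for _ in range(10_000):
        if mask.mean() >= target or rejected > 100:
            break
        p0 = rng.uniform(0, extent)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        rel = pts - p0
        proj = rel @ d
        dist2 = (rel**2).sum(axis=1) - proj**2
        cand = mask | (dist2 <= radius**2).reshape(shape)
        # keep the fraction as close to target as possible: skip a vessel
        # that would overshoot further than the current shortfall
        if abs(cand.mean() - target) <= abs(mask.mean() - target):
            mask = cand
            rejected = 0
        else:
            rejected += 1
    return mask


def gen_stack(spec: StackSpec) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic depth stack; returns (stack, ground-truth vessel mask).

    Vessel voxels carry the per-plane signal amplitude attenuated as
    exp(−n·z/EAL); the unlabeled background level is imposed from the
    theoretical SBR(z) of the sbr_model module (so stack-based measurements
    test the measurement code, not the optics simulation).  Poisson noise is
    added when ``noise`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _draw_vessels(spec, rng)
    z_um = np.arange(spec.nz) * spec.depth_step_um
    amp = spec.surface_signal * np.exp(-spec.order * z_um / spec.eal_um)
    depth_eals = np.maximum(z_um / spec.eal_um, 1e-3)
    prof = sbr_vs_depth(
        spec.order, StainingModel(chi=spec.chi), depth_eals, eal_um=spec.eal_um,
        wavelength_nm=920.0 if spec.order == 2 else 1320.0,
    )
    stack = np.empty((spec.nz, spec.ny, spec.nx))
    for i in range(spec.nz):
        bg = amp[i] / prof.sbr[i] if np.isfinite(prof.sbr[i]) else 0.0
        frame = np.full((spec.ny, spec.nx), bg)
        frame[mask[i]] += amp[i]
        stack[i] = frame
    if spec.noise:
        stack = rng.poisson(stack).astype(float)
    return stack, mask


def gen_depth_signal_table(
    eal_um: float,
    order: int,
    e0_nj: float,
    depths_um: np.ndarray | list[float],
    pulse_duration_s: float = 60e-15,
    cn: float | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Depth-resolved n-photon signal table following the power law.

    The focal pulse energy at depth z is e0·exp(−z/EAL); the detected signal
    per pulse is Cn·E^n/τ^(n−1).  ``cn`` defaults to the value that yields
    0.1 detected photon/pulse at the surface (the conventional operating
    point).  Multiplicative log-normal noise of coefficient ``noise_cv`` can
    be applied.  Columns: depth_um, signal_photons_per_pulse, power_mw.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    depths = np.asarray(depths_um, dtype=float)
    e_focus_j = e0_nj * 1e-9 * np.exp(-depths / eal_um)
    if cn is None:
        cn = 0.1 * pulse_duration_s ** (order - 1) / (e0_nj * 1e-9) ** order
    signal = cn * e_focus_j**order / pulse_duration_s ** (order - 1)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        signal = signal * rng.lognormal(0.0, noise_cv, size=signal.size)
    rep_rate_hz = 1e6
    return pd.DataFrame(
        {
            "depth_um": depths,
            "signal_photons_per_pulse": signal,
            "power_mw": e0_nj * 1e-9 * rep_rate_hz * 1e3,
        }
    )


def gen_photon_image(
    shape: tuple[int, int] = (256, 256),
    mean_photons: float = 0.5,
    conversion_factor: float = 40.0,
    offset: float = 100.0,
    read_noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-value image with known photon statistics.

    Pixel value = offset + factor·Poisson(mean) + Gaussian read noise; returns
    (image, true photon-count image).
    """
    rng = np.random.default_rng(seed)
    photons = rng.poisson(mean_photons, size=shape)
    img = offset + conversion_factor * photons + rng.normal(0.0, read_noise_sd, size=shape)
    return img, photons.astype(float)


def save_stack(path, stack: np.ndarray) -> None:
    """Write a depth stack as a multi-page TIFF (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def load_stack(path) -> np.ndarray:
    """Read a multi-page TIFF depth stack."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
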