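"""Nonlinear excitation scaling, attenuation fitting and 3PE saturation.

n-photon-excited signal per pulse follows S/f = Cn·(P/f)^n / τ^(n−1): quadratic
(n = 2) or cubic (n = 3) in pulse energy and inverse in pulse duration to the
(n−1)th power (sech² pulses assumed throughout).  Ballistic excitation power in
tissue decays as exp(−z/EAL), where the effective attenuation length combines
scattering and absorption.  From those two facts follow the depth scaling of
the surface pulse energy, the cross-over depth where a higher-order modality
becomes more power-efficient, and the EAL fit to a depth-resolved signal table.
Ground-state depletion (saturation) of a three-photon-excited fluorophore is
modelled from the per-pulse photon fluence at the focus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePlane",
    "PulseTrain",
    "WavelengthChannel",
    "CalibrationConstants",
    "SaturationParams",
    "EALFit",
    "signal_per_pulse",
    "calibrate_cn",
    "surface_pulse_energy",
    "fit_eal",
    "crossover_depth",
    "saturation_probability",
    "saturation_energy",
]

# Planck constant times speed of light, J·m
_HC = 6.62607015e-34 * 2.99792458e8


class ReferencePlane(str, Enum):
    """Plane at which a pulse energy is stated."""

    SURFACE = "surface"
    FOCUS = "focus"
    AFTER_OBJECTIVE = "after-objective"


@dataclass(frozen=True)
class PulseTrain:
    """A periodic pulse train characterised at a stated reference plane."""

    rep_rate_hz: float
    pulse_duration_s: float
    pulse_energy_j: float
    reference_plane: ReferencePlane = ReferencePlane.SURFACE

    def __post_init__(self) -> None:
        for name in ("rep_rate_hz", "pulse_duration_s", "pulse_energy_j"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def avg_power_w(self) -> float:
        return self.rep_rate_hz * self.pulse_energy_j


@dataclass(frozen=True)
class WavelengthChannel:
    """An excitation channel: wavelength, nonlinear order, attenuation length.

    Nominal EAL defaults used for depth normalisation are 293 μm for 1320 nm
    3PE and 154 μm for 920 nm 2PE (cortical gray matter).
    """

    wavelength_nm: float
    order: int
    eal_um: float

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        if not self.eal_um > 0:
            raise ValueError("eal_um must be > 0")


CHANNEL_2P_920 = WavelengthChannel(wavelength_nm=920.0, order=2, eal_um=154.0)
CHANNEL_3P_1320 = WavelengthChannel(wavelength_nm=1320.0, order=3, eal_um=293.0)


@dataclass(frozen=True)
class CalibrationConstants:
    """Coefficients Cn in S/f = Cn (P/f)^n / τ^(n−1) (detected photons/pulse).

    Units are whatever makes the right-hand side dimensionless in detected
    photons per pulse for pulse energy in J and duration in s.
    """

    c2: float = 0.0
    c3: float = 0.0

    def __post_init__(self) -> None:
        if self.c2 < 0 or self.c3 < 0:
            raise ValueError("coefficients must be non-negative")

    def coeff(self, order: int) -> float:
        if order == 2:
            return self.c2
        if order == 3:
            return self.c3
        raise ValueError("order must be 2 or 3")


@dataclass(frozen=True)
class SaturationParams:
    """Inputs of the 3PE ground-state-depletion model.

    ``gp3`` is the temporal coherence factor of a sech² pulse for third-order
    excitation; 0.51 reproduces the printed saturation energies together with
    NA_eff = 0.75 and τ = 60 fs.
    """

    sigma3_cm6s2: float = 3e-82
    na_eff: float = 0.75
    gp3: float = 0.51
    wavelength_nm: float = 1320.0
    pulse_duration_s: float = 60e-15

    def __post_init__(self) -> None:
        for name in ("sigma3_cm6s2", "na_eff", "gp3", "wavelength_nm", "pulse_duration_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.na_eff > 1.05:
            raise ValueError("na_eff must be <= 1.05")


def signal_per_pulse(
    train: PulseTrain, cal: CalibrationConstants, order: int
) -> float:
    """Detected photons per pulse, Cn·(P/f)^n / τ^(n−1)."""
    cn = cal.coeff(order)
    return cn * train.pulse_energy_j**order / train.pulse_duration_s ** (order - 1)


def calibrate_cn(
    measurements: list[tuple[float, float, float]], order: int
) -> CalibrationConstants:
    """Solve the excitation coefficient Cn from measured operating points.

    ``measurements`` holds (pulse_energy_j, pulse_duration_s, detected
    photons/pulse) rows.  A single row is solved exactly; several rows are
    combined by a least-squares fit of log Cn (i.e. the geometric mean of the
    per-row solutions), which weights multiplicative noise evenly.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if not measurements:
        raise ValueError("need at least one measurement")
    logs = []
    for energy, tau, signal in measurements:
        if energy <= 0 or tau <= 0:
            raise ValueError("pulse energy and duration must be > 0")
        if signal <= 0:
            raise ValueError("zero or negative signal cannot constrain Cn")
        logs.append(math.log(signal) - order * math.log(energy) + (order - 1) * math.log(tau))
    cn = math.exp(float(np.mean(logs)))
    if order == 2:
        return CalibrationConstants(c2=cn)
    return CalibrationConstants(c3=cn)


def surface_pulse_energy(
    e_focus_req_nj: float, depth_um: float, eal_um: float
) -> float:
    """Surface pulse energy that delivers ``e_focus_req_nj`` to depth ``depth_um``.

    Pure exponential attenuation: E_surface = E_focus · exp(depth / EAL).
    """
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    if not eal_um > 0:
        raise ValueError("eal_um must be > 0")
    return e_focus_req_nj * math.exp(depth_um / eal_um)


@dataclass(frozen=True)
class EALFit:
    """Result of :func:`fit_eal`."""

    eal_um: float
    surface_signal_per_pulse: float
    order: int
    depth_um: np.ndarray = field(repr=False)
    focus_power_fraction: np.ndarray = field(repr=False)


def fit_eal(depth_signal_table: pd.DataFrame, order: int) -> EALFit:
    """Fit the effective attenuation length from a depth-resolved signal table.

    Expects columns ``depth_um`` and ``signal_photons_per_pulse``.  The
    n-photon signal decays as exp(−n·z/EAL), so a linear fit of ln(signal)
    against depth has slope −n/EAL (equivalently, the common-log fit of the
    required pulse energy against depth has slope 1/(EAL·ln 10)).  The
    intercept gives the surface signal used for per-pulse normalisation, and
    the focus/surface power fraction is (S(z)/S(0))^(1/n).
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    z = np.asarray(depth_signal_table["depth_um"], dtype=float)
    s = np.asarray(depth_signal_table["signal_photons_per_pulse"], dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 depths")
    if np.any(np.diff(z) <= 0):
        raise ValueError("depth column must be strictly increasing")
    if np.any(s <= 0):
        raise ValueError("signals must be positive")
    slope, intercept = np.polyfit(z, np.log(s), 1)
    if slope >= 0:
        raise ValueError("signal does not decay with depth; cannot fit an EAL")
    eal = -order / slope
    s0 = math.exp(intercept)
    frac = (s / s0) ** (1.0 / order)
    return EALFit(
        eal_um=float(eal),
        surface_signal_per_pulse=float(s0),
        order=order,
        depth_um=z,
        focus_power_fraction=frac,
    )


def crossover_depth(
    e2_surface_nj: float, e3_surface_nj: float, eal2_um: float, eal3_um: float
) -> float:
    """Depth where equal-signal surface pulse energies of 2PE and 3PE coincide.

    With pure exponential attenuation, E_n(z) = E_n(0)·exp(z/EAL_n); the
    curves cross at z = ln(E3/E2) / (1/EAL2 − 1/EAL3).  Raises if the
    shorter-wavelength channel already needs the higher energy at the surface
    (no crossover).
    """
    if not (e3_surface_nj > 0 and e2_surface_nj > 0):
        raise ValueError("surface energies must be > 0")
    if not (eal3_um > eal2_um > 0):
        raise ValueError("require eal3 > eal2 > 0")
    if e3_surface_nj < e2_surface_nj:
        raise ValueError("e3 < e2 at the surface: no crossover depth exists")
    return math.log(e3_surface_nj / e2_surface_nj) / (1.0 / eal2_um - 1.0 / eal3_um)


def _focal_fluence_per_nj(p: SaturationParams) -> float:
    """Photons/cm² at the focus centre per nJ of focal pulse energy.

    Φ = E·π·NA²/(h·c·λ): the pulse's photon number E·λ/(hc) focused to the
    diffraction-limited area λ²/(π·NA²).
    """
    lam_m = p.wavelength_nm * 1e-9
    phi_per_j = math.pi * p.na_eff**2 / (_HC * lam_m)  # photons/m² per J
    return phi_per_j * 1e-9 * 1e-4  # per nJ, per cm²


def saturation_probability(e_focus_nj: float, p: SaturationParams) -> float:
    """Excitation probability per pulse for a molecule at the focus centre.

    Pr = 1 − exp(−gp3·σ3·Φ³/τ²) with Φ the per-pulse focal photon fluence.
    """
    if not e_focus_nj > 0:
        raise ValueError("e_focus_nj must be > 0")
    phi = e_focus_nj * _focal_fluence_per_nj(p)
    exponent = p.gp3 * p.sigma3_cm6s2 * phi**3 / p.pulse_duration_s**2
    return -math.expm1(-exponent)


def saturation_energy(pr: float, p: SaturationParams) -> float:
    """Focal pulse energy (nJ) giving excitation probability ``pr`` per pulse."""
    if not 0.0 < pr < 1.0:
        raise ValueError("pr must be in (0, 1)")
    exponent = -math.log1p(-pr)
    phi = (exponent * p.pulse_duration_s**2 / (p.gp3 * p.sigma3_cm6s2)) ** (1.0 / 3.0)
    return phi / _focal_fluence_per_nj(p)
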