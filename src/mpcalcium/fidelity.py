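"""Shot-noise-limited discriminability of calcium transients.

With a photon-counting detector the noise on a fluorescence trace is Poisson,
so the detectability of a single-action-potential calcium transient is fixed by
the baseline photon rate ``F0``, the indicator's peak fractional change ΔF/F,
and its 1/e decay time τ.  For an exponentially decaying transient the
signal-detection index is

    d' = (ΔF/F) · sqrt(F0 · τ / 2)

and a time-invariant background B = F0/SBR inflates both baseline and variance,
reducing d' by sqrt(1 + 1/SBR).  The functions here evaluate that index, invert
it for the minimum photon budget, convert d' to detection operating points
under an equal-variance Gaussian two-class model, and quantify the pulse
pile-up (photon stacking) undercount of a photon-counting chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "IndicatorParams",
    "DetectionBudget",
    "GCAMP6S",
    "dprime",
    "min_baseline_rate",
    "detection_rates",
    "stacking_error",
]


@dataclass(frozen=True)
class IndicatorParams:
    """Calcium-indicator kinetics and sensitivity.

    Parameters
    ----------
    dff_single_ap : float
        Peak fractional fluorescence change ΔF/F of a single-action-potential
        transient (dimensionless, > 0).
    tau_decay_s : float
        1/e decay time of the transient in seconds (> 0).
    name : str
        Free-form label.
    """

    dff_single_ap: float
    tau_decay_s: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.dff_single_ap > 0:
            raise ValueError("dff_single_ap must be > 0")
        if not self.tau_decay_s > 0:
            raise ValueError("tau_decay_s must be > 0")


#: GCaMP6s defaults: ΔF/F ≈ 30% per AP, τ1/e ≈ 2 s.
GCAMP6S = IndicatorParams(dff_single_ap=0.30, tau_decay_s=2.0, name="GCaMP6s")


@dataclass(frozen=True)
class DetectionBudget:
    """A (baseline rate, SBR, d') triple describing one operating point."""

    f0_photons_per_s: float
    sbr: float
    d_prime: float

    def __post_init__(self) -> None:
        if self.f0_photons_per_s < 0:
            raise ValueError("f0_photons_per_s must be >= 0")
        if not self.sbr > 0:
            raise ValueError("sbr must be > 0")
        if self.d_prime < 0:
            raise ValueError("d_prime must be >= 0")


def dprime(
    ind: IndicatorParams, f0_photons_per_s: float, sbr: float = math.inf
) -> float:
    """Discriminability index of a single transient.

    d' = (ΔF/F)·sqrt(F0·τ/2) / sqrt(1 + 1/SBR).  ``sbr=inf`` recovers the
    background-free expression.
    """
    if f0_photons_per_s < 0:
        raise ValueError("f0_photons_per_s must be >= 0")
    if not sbr > 0:
        raise ValueError("sbr must be > 0")
    base = ind.dff_single_ap * math.sqrt(f0_photons_per_s * ind.tau_decay_s / 2.0)
    return base / math.sqrt(1.0 + 1.0 / sbr)


def min_baseline_rate(
    ind: IndicatorParams, d_target: float, sbr: float = math.inf
) -> float:
    """Baseline photon rate F0 (photons/s) needed to reach ``d_target``.

    Exact closed-form inverse of :func:`dprime`; a finite SBR multiplies the
    background-free requirement by (1 + 1/SBR).
    """
    if d_target < 0:
        raise ValueError("d_target must be >= 0")
    if not sbr > 0:
        raise ValueError("sbr must be > 0")
    f0_free = 2.0 * (d_target / ind.dff_single_ap) ** 2 / ind.tau_decay_s
    return f0_free * (1.0 + 1.0 / sbr)


def detection_rates(d_prime: float) -> tuple[float, float]:
    """(true-positive rate, false-positive rate) at discriminability ``d_prime``.

    Equal-variance Gaussian two-class model with the decision threshold midway
    between the class means: TPR = Φ(d'/2) and FPR = 1 − Φ(d'/2).  At d' = 3
    this gives the familiar 93% / 7% operating point.
    """
    if d_prime < 0:
        raise ValueError("d_prime must be >= 0")
    tpr = float(norm.cdf(d_prime / 2.0))
    return tpr, 1.0 - tpr


def stacking_error(count_ratio: float | np.ndarray) -> float | np.ndarray:
    """Fractional undercount from photon stacking (pulse pile-up).

    A counter that registers at most one photon per laser pulse undercounts a
    Poisson source by 1 − (1 − exp(−λ))/λ, where λ is the mean detected count
    per pulse (count rate / repetition rate).  The limit for λ→0 is λ/2 → 0.
    """
    lam = np.asarray(count_ratio, dtype=float)
    if np.any(lam < 0):
        raise ValueError("count_ratio must be >= 0")
    out = np.where(
        lam > 1e-12,
        1.0 - (-np.expm1(-lam)) / np.where(lam > 1e-12, lam, 1.0),
        lam / 2.0,
    )
    if np.isscalar(count_ratio) or np.ndim(count_ratio) == 0:
        return float(out)
    return out
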