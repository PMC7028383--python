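# mpcalcium

Quantitative models for planning deep two-photon (2PM, 920 nm) and
three-photon (3PM, 1320 nm) calcium imaging in the mouse brain: how many
photons a neuron must yield for reliable transient detection, how much pulse
energy that costs at depth, how hot the tissue gets, and where out-of-focus
background ends the useful depth range of 2PM.

The package is aimed at microscopists and methods developers who need to
budget an experiment before building it: every constraint is an explicit,
testable computation rather than a rule of thumb.

## The models

**Detection fidelity.** With photon-counting detection the noise is Poisson,
so a single calcium transient with peak fractional change ΔF/F and 1/e decay
time τ riding on a baseline rate F₀ has discriminability

    d' = (ΔF/F) · √(F₀ τ / 2),

reduced by √(1 + 1/SBR) when a time-invariant background is present. Under an
equal-variance Gaussian two-class model with a midpoint threshold, TPR =
Φ(d'/2) and FPR = 1 − Φ(d'/2).

**Excitation scaling.** n-photon signal per pulse follows
Sₙ/f = Cₙ (P/f)ⁿ / τⁿ⁻¹; ballistic power decays as exp(−z/EAL). From these
follow the surface pulse energy needed at depth, the EAL fit to a depth
stack, the 2PE/3PE cross-over depth ln(E₃/E₂)/(1/EAL₂ − 1/EAL₃), and the 3PE
ground-state-depletion (saturation) probability
Pr = 1 − exp(−g_p(3) σ₃ Φ³/τ²) with Φ = E·πNA²/(hcλ).

**Tissue heating.** A weighted Monte Carlo simulation (Henyey–Greenstein
scattering, implicit-capture absorption) propagates photons from an
underfilled NA 1.05 objective through a scanned focus and tallies absorbed
power on an axisymmetric grid, which drives a Pennes bio-heat solver
(conduction + blood-perfusion sink + metabolic heat) with a cooled cranial
window at the surface.

**Signal-to-background depth limit.** Out-of-focus n-photon excitation is
integrated over the ballistic cone plus a multiply-scattered halo; with
staining inhomogeneity χ = Ĉ/⟨C⟩ the SBR falls below 1 at ~4.7 EALs for 2PM
at χ = 50 (≈2% labeled volume).

**Measurement pipeline.** Pixel→photon conversion with histogram-mode
calibration, Hamming-window filtering, ΔF/F normalisation, Poisson
likelihood-ratio spike inference (threshold ln((1−r)/r)), and per-transient
2P/3P ΔF/F ratios. A synthetic-data module generates traces, vasculature
stacks and depth-signal tables with known ground truth.

## Worked example

```python
from mpcalcium import fidelity as fi, excitation as ex, planner as pl
from mpcalcium.fidelity import GCAMP6S

f0 = fi.min_baseline_rate(GCAMP6S, d_target := 3.0)
tpr, fpr = fi.detection_rates(d_target)
e_surface = ex.surface_pulse_energy(1.86, depth_um=586, eal_um=293)
rate = pl.max_rep_rate(p_thermal_mw=100, e_surface_nj=e_surface)
print(f"F0 = {f0:.0f} photons/s -> {tpr:.1%} TPR / {fpr:.1%} FPR")
print(f"surface pulse energy {e_surface:.1f} nJ, max rep rate {rate/1e6:.1f} MHz")
```

prints

```
F0 = 100 photons/s -> 93.3% TPR / 6.7% FPR
surface pulse energy 13.7 nJ, max rep rate 7.3 MHz
```

i.e. a GCaMP6s neuron must deliver ~100 photons/s of baseline signal for
d' = 3 (93% true / 7% false positives); imaging it two attenuation lengths
deep costs ~14 nJ per pulse at the brain surface, and a 100 mW thermal budget
then caps the repetition rate near 7 MHz.

The `analysis/` scripts run the full study end to end — photon budgets,
attenuation fits, photon fates, heating sweeps, SBR profiles, trace
statistics and imaging plans — writing tables under `results/`.

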