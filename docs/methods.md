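# Methods

This note records the models implemented in `mpcalcium`, their assumptions,
the defaults that matter, and the choices made where the design was genuinely
open. Everything quantitative stated here is computed by the test suite or
the analysis scripts; nothing is asserted that the code does not reproduce.

## Transient discriminability (`fidelity`)

A calcium transient is modelled as an instantaneous rise by ΔF/F followed by
exponential decay with time constant τ, on a baseline photon rate F₀ with
Poisson noise. Matched filtering of the whole transient gives
d' = (ΔF/F)·√(F₀τ/2); the expression assumes the frame rate samples the
decay (a warning is raised below 5 Hz for GCaMP6s) and that ΔF/F is not
large (the Gaussian approximation of the Poisson log-likelihood statistic;
at ΔF/F = 0.3 the error is below 2%, verified against simulation).

Detection rates convert d' through an equal-variance Gaussian two-class
model with the decision threshold midway between the class means:
TPR = Φ(d'/2), FPR = 1 − Φ(d'/2). The midpoint-threshold convention is a
reconstruction — it is the symmetric-cost choice and reproduces the familiar
93%/7% operating point at d' = 3 (Φ(1.5) = 0.933). Whether the published
operating point assumed a per-frame or whole-transient statistic is not
stated anywhere we can check; the whole-transient reading is adopted because
it is the one consistent with the d' formula itself.

Background at signal-to-background ratio SBR enters as a time-invariant rate
B = F₀/SBR: it inflates the baseline to F₀(1+1/SBR) without adding signal,
reducing d' by √(1+1/SBR) and the apparent ΔF/F by (1+1/SBR)⁻¹. Multi-AP
bursts are represented by passing a larger ΔF/F rather than by an explicit
burst model.

Photon-counting pile-up ("stacking") error: a counter that registers at most
one photon per laser period undercounts a Poisson source of mean λ per
period by 1 − (1−e^{−λ})/λ, ≈ λ/2 for small λ. Keeping the count rate below
5% of the repetition rate bounds the undercount at 2.5%.

## Excitation scaling and saturation (`excitation`)

Signal per pulse: Sₙ/f = Cₙ(P/f)ⁿ/τⁿ⁻¹ for n = 2, 3, with sech² pulses
assumed throughout. Cₙ is calibrated from measured (pulse energy, duration,
signal) points; multiple points are combined as the geometric mean of the
per-point solutions, which is the least-squares answer on the log scale and
weights multiplicative noise evenly.

EAL fitting regresses ln(signal) on depth; the slope is −n/EAL for an
n-photon signal. (The equivalent common-log formulation — slope ln(10)/EAL
for the log₁₀ of the required pulse energy — is the convention used for
printed attenuation plots; the two are the same line in different units.)
The focus/surface power fraction is (S(z)/S(0))^{1/n}.

The cross-over depth between two modalities whose equal-signal surface
energies are E₂(0) < E₃(0) under attenuation lengths EAL₂ < EAL₃ is the
closed form ln(E₃/E₂)/(1/EAL₂ − 1/EAL₃). On the measured GCaMP6s surface
energies (0.24 vs 1.86 nJ) and attenuation lengths this evaluates to
~646–665 μm depending on which EAL pair is used; measured in vivo curves
put it around 700 μm. The closed form is the implemented definition; the
in vivo number is a measurement outcome, not a target of this package.

Saturation: the per-pulse excitation probability of a molecule at the focus
centre is Pr = 1 − exp(−g_p(3)·σ₃·Φ³/τ²) with focal photon fluence
Φ = E·πNA²/(hcλ). Defaults σ₃ = 3×10⁻⁸² cm⁶s², NA_eff = 0.75, τ = 60 fs,
g_p(3) = 0.51 reproduce the 2 nJ (10%) and 4.3 nJ (63%) saturation energies
to ~1%; the exact NA and pulse-shape factor behind those printed values are
not stated, so both are configurable and the acceptance band is ±15%.

Pulse energies are tagged with a reference plane (surface / focus /
after-objective). After-objective → surface conversion is immersion-water
absorption (see heating); focus → surface is the EAL exponential.

## Light transport (`mc_transport`)

Weighted Monte Carlo in the MCML tradition: exponential free paths at
μt = μa + μs, Henyey–Greenstein scattering with g = 0.9, implicit-capture
absorption depositing weight·μa/μt per collision into an axisymmetric
(z, r) voxel grid (25 μm pitch by default). Instead of Russian roulette the
residual weight (≤10⁻⁶) is deposited at its last collision site, which makes
weight conservation exact at a bias bounded by the threshold; the analog
(unweighted) oracle in the test suite confirms the fates to Monte Carlo
error. Layered media are handled exactly by truncating any free path at a
layer interface and redrawing there (memorylessness of the exponential).

Launch geometry: the objective (NA 1.05, f = 7.2 mm) is underfilled to 70%
of its back aperture by a Gaussian beam, giving effective NA ≈ 0.75. A
photon's back-aperture radius is sampled as w = w₀√(−ln u/2), its polar
angle is arcsin(w/(n₀f)), and it enters the surface at radius tan(θ)·z so
that all rays converge on the focus. Scanning a 230-μm FOV is modelled by
sampling focal positions uniformly over the FOV disk — equivalent to
time-averaged illumination because tissue cools at only ~0.1 °C/s between
frame revisits (the `scan_fluctuation` estimate: 0.05 °C ripple at 2 Hz).

Boundaries: photons crossing the top surface exit (no Fresnel reflection;
tissue n 1.36 ≈ water 1.33) and are classified by exit radius — within the
2.5-mm cranial window or onto the surrounding skull; photons travelling
beyond 6 mm laterally or in depth escape. Gray-matter optical parameters
(per mm): μa 0.039/0.078/0.12 and μs 6.7/3.2/3.2 at 920/1280/1320 nm.

With this geometry the absorbed ("heating") fractions at 1 mm focal depth
are ~62.5% at 1320 nm and ~48.5% at 1280 nm, matching the published 63/49
within Monte Carlo error. At 920 nm this model gives ~30.5% versus a
published 20%: the pairwise sums heating+escaped and window+skull both
match, so the difference sits in the exit classification and recirculation
at the surface — i.e. in the explicit window-glass/skull layer geometry of
the original simulation, which is not described in the material available
to us and is deliberately not invented here. The discrepancy is confined to
the most scattering-dominated wavelength, where photons make many surface
encounters; it is documented as a known limitation rather than tuned away.

## Brain heating (`bioheat`)

The Pennes bio-heat equation
ρc ∂T/∂t = k∇²T + ρ_b c_b w_b (T_A − T) + Sh + q_m is solved on the
transport grid by finite differences: the steady state as one sparse linear
solve, transients by implicit Euler (unconditionally stable, so no CFL
restriction arises). Thermal parameters are the standard gray-matter set
(k = 0.527 mW/mm·°C, perfusion ρ_b c_b w_b = 0.0324 mW/mm³·°C,
q_m = 9.5×10⁻³ mW/mm³, T_A = 36.7 °C), giving the closed-form checks the
solver must hit: uniform perfusion balance at 36.99 °C and the perfused
point-source kernel exp(−r/L)/(4πkr) with L = √(k/ρ_b c_b w_b) ≈ 4.0 mm.

Boundary conditions: the surface under the window is Dirichlet at a
configurable sub-body temperature (default 30 °C) representing window heat
loss; the surface under the skull is insulated; distant bounds sit at T_A.
The window temperature is the model's one free calibration parameter — it
shifts absolute maximum temperatures (and hence the exact 37 °C/41 °C
crossing powers) but barely moves power slopes. The absorbed-power source
is mapped to solver nodes by volume-weighted averaging of adjacent voxels
so that integrated power is preserved even for concentrated deposits.

The reported maximum temperature is the average over a cylinder of 120 μm
radius × 210 μm height (~10⁷ μm³) centred on the on-axis peak — the hottest
contiguous volume around the scanned area. For continuous 1320-nm scanning
at 1 mm depth and 230 μm FOV the model yields: Tmax flat near 36.7 °C at
low power (absorption first offsets window cooling), crossing 37 °C at
~86 mW after the objective, then rising ~2.4 °C per 50 mW — inside the
2–4 °C/50 mW acceptance window around the published ~3, with the residual
gap sharing the same window-geometry caveat as above. The after-objective →
surface conversion uses water absorption over a 1.02-mm default path
(80 → 68 mW at 1320 nm); at 920 nm water absorption is taken as 0.0056/mm
(pure-water value — the tissue μa at 920 nm is not water-dominated, so the
75%-of-water rule used above 1200 nm does not apply), making the 920-nm
correction <2% over 2 mm.

## SBR versus depth (`sbr_model`)

The depth limit of 2PM in non-sparse samples is set by out-of-focus
excitation. The implemented background model integrates, plane by plane,
the nth power of the combined intensity of two coaxial Gaussian components:

* the **ballistic cone** of the focused beam (waist w₀ = λ/πNA, Rayleigh
  range z_R), carrying power e^{−z/EAL};
* a **scattered halo** carrying the absorption-only remainder
  e^{−μa z} − e^{−z/EAL}, with 1/e² radius √2·θ_rms·z/√3·√max(1, μs z)
  from a small-angle random walk (θ_rms = √(2(1−g)) per scattering event).

The in-focus slab |ζ| ≤ 2.5 z_R (the axial extent of a small labeled
structure) weighted by the peak concentration Ĉ is the signal; everything
else weighted by ⟨C⟩ is background; SBR = χ·signal/background with
χ = Ĉ/⟨C⟩. Binary staining makes χ ≈ 1/volume-fraction.

Two reconstruction decisions matter. First, a ballistic-only cone model —
the naive reading — places the 2PE SBR = 1 depth near 7 EALs for χ = 50,
far deeper than the established ~4.7; the scattered halo is what supplies
the missing background, because by mid-depth nearly all surviving power is
scattered yet still concentrated within a few hundred μm of the axis.
Second, the halo must *not* be floored at the converging cone radius:
scattered photons cannot refocus, and a variant that let them do so put
spurious scattered power into the focal slab. With the natural parameter
values (no tuned coefficients) the model yields SBR = 1 at 4.65 EALs for
χ = 50 (benchmark ~4.7, accepted band 4.0–5.4) and shallow-depth SBR of
order 10², consistent with surface measurements (~100). The 3PE profile
dominates the 2PE profile at every depth for identical EAL and staining.

Measurements: SBR per frame is (mean of brightest 0.1% pixels − background)
/ background, with background averaged over unlabeled regions; 0.5% is the
convention for attenuation curves (caller-selectable). Staining statistics
use per-frame Otsu thresholding (the standard gray-threshold segmentation);
χ = 1/fraction under the binary assumption. Aberration-induced SBR loss
beyond the white matter is outside the model.

## Trace pipeline (`trace_pipeline`)

Pixel values convert to photons as (pixel − offset)/factor; the calibration
helper finds the offset (zeroth mode) and single-photon (first mode) peaks
of the pixel histogram, with smoothing and a prominence gate so sampling
noise between modes is not mistaken for a mode.

Traces are low-pass filtered with a unit-gain Hamming window (0.37 s
default), reflect-padded so a constant trace stays exactly constant. The
baseline F₀ is the mean of the smoothed trace after excluding detected
events and one filter span before each onset, iterated three times from a
median start; output is (F − F₀)/F₀.

Spike inference is a reconstruction specified only by its threshold: each
frame k is scored with the log-likelihood ratio of Poisson rates
F₀(1 + a_j) vs F₀ along an exponential-decay template a_j truncated at 3τ,
and thresholded at C = ln((1−r)/r), with the firing rate r estimated as the
fraction of the smoothed normalised trace >1.5 SD above its mean (clamped
into (0, 0.5) with a warning). Contiguous supra-threshold runs merge into
one event. The statistic's separation (μ₁−μ₀)/σ₀ equals the analytic d' for
small ΔF/F, and its simulated operating characteristic matches
Φ(d'/2)/1−Φ(d'/2) within sampling error at d' ∈ {1, 2, 3} — the
consistency check tying this module to the fidelity module.

ΔF/F ratios between simultaneous channels: peaks >30% ΔF/F in the 3P trace
(with distance and prominence gates rejecting noise bumps on a decay) are
matched to the 2P channel's local maximum within ±0.5 s; the ratio list and
the Pearson correlation of the normalised traces are reported. The measure
is invariant to a common gain.

## Planner (`planner`)

Plans are assembled in constraint order: focal pulse energy at the top of
the nonlinear-safe range (default 1–2 nJ; ~10 nJ ablates), surface energy
via exp(depth/EAL), repetition rate = thermal power budget / surface pulse
energy (optionally floored to a laser divider), then the pixel grid — two
pixels per focal spot, capped by the pixel throughput the repetition rate
supports at ≥5 Hz — with an exactly integer number of pulses per pixel.
Infeasible constraint sets raise an error naming the binding constraint.
The default thermal-budget lookup is a quasi-linear trend anchored at
~100 mW/600 μm and ~120 mW/1 mm; regenerating it from this package's own
bioheat sweeps is the intended workflow for a specific preparation.
Adaptive excitation (pulses delivered to ROIs only) enters as an effective
duty-cycle factor on the average power. The wavelength trade-off combines
power headroom (√ gain in d' at fixed peak intensity) with the indicator
sensitivity factor; 1280 nm's ×1.5 power but ×0.5 ΔF/F gives d' ×0.61,
favouring 1320 nm.

## Synthetic data (`synthetic_data`)

Traces: per-frame Poisson counts around F₀(1 + Σ ΔF/F·e^{−(t−t_k)/τ}) + B,
with explicit or Poisson-drawn spike times; paired channels share one spike
train with independent noise. Stacks: straight random cylinders (<20 μm
diameter) added until the labeled fraction meets the 2% target (a candidate
that would overshoot further than the current shortfall is skipped);
per-plane amplitude e^{−nz/EAL}; the background floor is imposed from the
theoretical SBR(z) rather than simulated optically, so stack tests isolate
the measurement code. Depth tables evaluate the power law exactly with
optional log-normal noise. All generators are seed-driven and
bit-reproducible.

What the generators do *not* emulate: realistic angiogram topology, neuropil
texture, motion, indicator nonlinearity, and white-matter aberration. A
passing round-trip therefore demonstrates correctness of the measurement
chain under the stated noise model, not robustness to everything real data
can do.

## Problem sizes and numerics

Default problem sizes: transport runs of 1.5–4×10⁵ photons in the test
suite and 10⁶ in the acceptance script (binomial error ≤0.15 percentage
points on fate fractions, far below the ±3-point bands); bio-heat solves on
240×240 (25 μm) axisymmetric grids, with the hottest-volume metric stable
to <0.1 °C under 2× grid refinement; SBR integrals on ~3000 axial planes
with closed-form radial integration of the two-Gaussian intensity. Degenerate
inputs (zero signal, empty masks, flat frames, all-spike traces,
non-monotone depth columns) raise explicit errors rather than returning
silent defaults.
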