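# Methods

## Spin-physics simulation

Metabolites are modeled as groups of magnetically equivalent protons with
chemical shifts δ (ppm, water = 4.70 ppm) and scalar couplings J (Hz)
between groups. The engine builds the full product-space Hamiltonian
H = Σᵢ 2π νᵢ Iᵢz + Σᵢ<ⱼ 2π Jᵢⱼ Iᵢ·Iⱼ (rotating frame at the carrier,
νᵢ = (δᵢ − δ_carrier)·f₀ with f₀ = 127.73 MHz, the nominal 3 T proton
frequency — chosen so that a 0.05 ppm shift difference corresponds to
6.4 Hz) and evolves the density matrix through an idealized sequence:
instantaneous 90°ₓ excitation, delays via the eigendecomposition of H, and
instantaneous π_y refocusing pulses. Detection at the echo top yields a
line list (frequency, complex amplitude) normalized so an uncoupled
n-proton group integrates to n.

Choices and consequences:

* **Pulses are ideal rotations.** Adiabatic waveforms, B1 profiles and
  finite pulse widths are not simulated; the TE-dependence of multiplets is
  timing + bandwidth physics, which is what the simulation is for.
* **Relaxation during the sequence is neglected**, so multiplet amplitude
  versus TE is pure J-modulation. In vivo, T₂ decay additionally attenuates
  long-TE signal; the quantification module applies that correction
  separately as a static factor.
* **Coupled clusters are simulated independently.** Groups connected by
  nonzero J form a cluster simulated in its own product space (capped at 8
  spins, 6 groups); an uncoupled group is emitted analytically as a
  TE-independent singlet. This keeps nine-proton singlets (choline) exact
  and cheap.
* **Weak-coupling anchor.** For a two-group pair the integrated doublet
  amplitude follows N·cos(πJTE); the engine matches this to ~10⁻¹⁰ when
  J/(2Δν) ≲ 10⁻⁶ and deviates at first order in J/(2Δν) otherwise. At 3 T,
  lactate (J/Δν ≈ 0.02) therefore inverts to −0.998 rather than the
  closed-form −0.9997 at TE 144 ms — a real second-order effect, and the
  reason the full-inversion test asserts ≤ −0.99 rather than ≤ −0.999.
* **sLASER timing** uses four refocusing pulses at symmetric sub-echo
  fractions (timings are not part of the published protocol); with ideal
  all-spin refocusing the result is timing-insensitive except for
  second-order coupling terms.
* **PRESS sub-echo fractions default to (0.2, 0.8)** — the short-TE₁
  asymmetric timing of clinical PRESS. The displacement model partitions
  each observed group's (fully selected) voxel into sub-regions where each
  coupling partner is refocused by both, one, or neither π pulse, with
  displacement fractions (Δf_partner − Δf_observed)/bandwidth per direction;
  every sub-region is evolved exactly with group-selective pulses, and
  coherence selection keeps, at detection, only groups refocused by both
  pulses (crushers dephase the rest). With symmetric PRESS timing the two
  single-pulse regions contribute cos(πJ·TE/2) terms that vanish at
  TE = 144 ms for lactate, and the characteristic intensity ordering
  |amp(144)| < |amp(288)| disappears; the asymmetric default reproduces it
  robustly. Convergence to the ideal spectrum is first-order in
  1/bandwidth, so "effectively infinite" in tests means 10⁹ Hz.
* **Preset library.** Lactate CH₃ 1.31 ppm / CH 4.10 ppm, J = 7 Hz; β-OHB
  CH₃ 1.19 ppm / CH 4.13 ppm, J = 6.3 Hz (the CH₂ resonances are omitted —
  they underlie crowded regions and carry no quantitative claim here);
  acetoacetate two singlets 2.27 / 3.34 ppm (the second peak is also
  reported at 3.43 ppm; `get_system("acac", acac_second_peak=3.43)`
  overrides it); acetone one singlet 2.22 ppm. NAA, Cr, Cho, myo-inositol,
  Glx, glycine and alanine are deliberately simplified (dominant resonances,
  weak-coupling-level multiplets) — adequate for crowded-spectrum fitting
  exercises, not for strong-coupling fidelity of glutamate at short TE.
* **Rendering.** Lines are rendered analytically as complex Lorentzians
  (unit real-part area, R = π·fwhm) or Gaussians (Faddeeva function); FIDs
  are synthesized as damped complex exponentials consistent with the
  continuous Fourier transform of the rendered profile. Basis entries are
  per-proton normalized (each metabolite's lines divided by its total
  proton count), so one fitted amplitude unit corresponds to
  1 mM · N_protons · relaxation factor in the generator's units.
* **Doublet geometry measurements** (splitting, midpoint) peak-pick the
  magnitude spectrum: at TE 40 ms roughly equal in-phase and antiphase
  components coexist, and dispersion admixture shifts real-part maxima by
  ~0.25 Hz, while magnitude maxima stay at the line positions.

## Synthetic data generator

The generator emulates the study acquisitions: 2D ¹H sLASER CSI at
TE 144 ms / TR 2000 ms, 20×20 grid over 240×240 mm² (6×6×12 mm³ voxels),
2000 Hz bandwidth, 1024 points; a 2°-flip TR 200 ms unsuppressed water
reference; a smooth center-bright B1 map (0.9–1.1); a 3D ³¹P FID CSI; and
three-class tumor masks. Tests run the same machinery on 8×8 or 4×4 grids
with proportionally smaller tumors — the per-voxel physics is identical and
the statistics are per-voxel, so the problem size only controls runtime.

* **Compartments** (nested discs: necrotic core ⊂ contrast-enhancing rim ⊂
  edema ⊂ NAWM) carry baseline concentrations with lactate
  4.92 mM in tumor vs 1.80 mM in NAWM and total choline 1.90 vs 1.57 mM;
  NAA/Cr/mI/Glx defaults are white-matter-typical values. Session 2 keeps
  the geometry and baseline concentrations (metabolites "not expected to
  change" truly do not) and adds ketone bodies to the necrotic core and
  enhancing rim at 0.35 mM per mL of necrotic-core volume
  (AcAc = 0.5·β-OHB, Ace = 0.25·β-OHB), optionally with relative Gaussian
  jitter — the linear rule that the downstream volume-correlation analysis
  probes. The default 20×20 scene yields β-OHB ≈ 2.0 mM, AcAc ≈ 1.0 mM.
* **Per-voxel spectra** are Σₘ Cₘ·Rₘ·Nₘ·basisₘ rendered at the compartment
  linewidth (default 5.7 Hz, the canonical in-vivo mean), plus a broad
  Gaussian baseline hump centered at 3.5 ppm (0.5 ppm wide) for voxels in or
  8-adjacent to necrosis — a stand-in for the insufficient water suppression
  observed near large necrotic areas — plus circular complex Gaussian noise
  drawn in the time domain.
* **Noise calibration.** The default noise level (`noise_sigma = 0.022`,
  frequency-domain real-part sd in basis units) is set so the fitted NAWM
  Cramér–Rao bounds land at the protocol-typical single-digit values
  (NAA ≈ 4%, Cr ≈ 5%, Cho ≈ 5–6%, lactate ≈ 25–30%), i.e. the generator's
  "protocol noise" reproduces the study's reported NAWM uncertainty levels
  rather than an arbitrary SNR. The ³¹P default
  (`DEFAULT_P31_NOISE_SIGMA = 0.08` per time sample) gives PCr relative SDs
  around 2%.
* **Water reference** per voxel: water_content × 2 × 55 510 mM ×
  exp(−TE_w/T₂*_w) seen through the spoiled-GRE steady state
  sin(αB1)(1−E1)/(1−cos(αB1)E1). Water contents default to NAWM 0.70,
  edema/enhancing tumor 0.85, necrosis 0.95 (configurable; the study's
  supplementary constants are not public).
* **What the generator does *not* emulate:** anatomy, the CSI spatial
  response/point-spread function, k-space weighting, motion, scalp-lipid
  contamination, eddy currents, frequency drift. Passing tests therefore
  demonstrate the correctness and calibration of the analysis chain under
  its own forward model — not robustness to every artifact of real data.

## Linear-combination fitting

Variable projection: amplitudes (non-negative) and cubic-spline baseline
coefficients (knots every 0.15 ppm over the 0.5–4.2 ppm window) are solved
by bounded linear least squares inside a trust-region search over three
global nonlinear parameters — frequency shift (±0.1 ppm), zero-order phase
(±30°), and one extra Lorentzian damping (0–10 Hz) shared by all
metabolites. The real part after phasing is fit; macromolecules are not
modeled (the long TE suppresses them; the spline absorbs the residual 3–4
ppm distortion). Noise is estimated as the sd of the phased real part in
the signal-free 9–10 ppm window.

CRLBs come from the Fisher matrix of the full Jacobian (amplitudes,
baseline coefficients, and numeric derivatives for the three nonlinear
parameters); near-singular information (duplicate basis entries) yields
infinite CRLBs for the metabolites involved, and amplitudes at the
non-negativity floor are reported as not detected. Linewidth is the FWHM
of the tallest fitted peak measured on the magnitude of an 8×-resampled
model curve (doublets are inverted at long TE); SNR is that peak over the
residual noise sd. Because the reported CRLB% divides by the *fitted*
amplitude, single-replicate CRLB% values scatter with 1/â — recovery and
detectability claims are therefore Monte-Carlo statements over seeded
replicates.

Rejection gates: whole-voxel rejection for linewidth > 0.1 ppm, best
metabolite SNR < 3, or a manual artifact flag (visual artifact judgment is
represented only as this override); per-metabolite acceptance requires
CRLB strictly below 10% (NAA, Cr, Cho), 25% (Glx), 40% (lactate,
myo-inositol), 80% (ketone bodies), 50% otherwise.

## ³¹P fitting

Fifteen exponentially decaying sinusoids over the standard species: PCr
(0 ppm reference), Pi (pH-dependent shift), PE 6.78, PC 6.24, GPE 3.50,
GPC 2.95 ppm, ATP as γ/α doublets and β triplet (J_PP = 16.1 Hz) with one
shared amplitude, and two broad macromolecule components (2.2 and
−8.3 ppm, 120 Hz) — 1+1+1+1+1+1+7+2 = 15 lines; the exact split among
species follows the common brain-³¹P prior-knowledge convention and is
configurable. The fit is trust-region nonlinear least squares in the time
domain with an analytic Jacobian, per-species shift windows and damping
bounds, a shared zero-order phase, and non-negative amplitudes. Relative
SDs are Cramér–Rao values from the Fisher matrix; residual flatness is the
lag-1 autocorrelation of the real residual.

pH = 6.75 + log₁₀((δ − 3.27)/(5.69 − δ)) with δ the fitted Pi shift
relative to PCr — the conventional Henderson–Hasselbalch calibration; the
constants are configurable since calibrations differ between laboratories.
PME/PDE = (PC+PE)/(GPC+GPE); ATP/PCr uses the γ-ATP amplitude. Compartment
presets: tumor pH 7.08, PME/PDE 0.71, ATP/PCr 0.69; NAWM pH 7.03,
PME/PDE 0.51, ATP/PCr 0.67.

## Quantification

C = (Sₘ/S_w)·(2/Nₘ)·55 510 mM·water_content·(R_w/Rₘ), with
Rₘ = exp(−TE/T₂ₘ)(1 − exp(−TR/T₁ₘ)) at the spectroscopy TR/TE and
R_w = exp(−TE_w/T₂*_w) at the water-reference echo time (the water T₁
saturation is inverted out of S_w via the B1-scaled steady-state factor).
Relaxation defaults (3 T): NAA 1470/247 ms, Cr 1460/152 ms,
Cho 1300/207 ms, water 1000/80 ms; ketone bodies and unlisted metabolites
use the NAA values; a single table serves tumor and NAWM alike. A
configurable slice-profile scale (default 1.0) absorbs the
metabolite/water slice-thickness mismatch. Partial-volume and CSF
corrections are out of scope.

## Statistics

Differences are S2 − S1 throughout. Wilcoxon signed-rank: zero differences
dropped, mid-ranks for ties, exact enumeration of all 2ⁿ sign assignments
for n ≤ 15, normal approximation with continuity and tie correction above.
Bland–Altman: bias ± 1.96·sd (sample sd). CV: per-subject sample-sd/mean
averaged across subjects (the population-vs-sample convention is not fixed
by the protocol; sample sd chosen). Spearman ρ with mid-ranks; exact
permutation p for n ≤ 10 (streamed enumeration), t-approximation above. No
multiple-testing correction is applied, and reports say so. The
ketone-body/volume analysis correlates per-subject mean accepted tumor
concentrations with mask volumes (voxel count × voxel volume).

## Numerical notes and degenerate inputs

All-zero spectra are flagged degenerate and skipped; constant inputs to
Spearman raise; fewer than 2 pairs (Bland–Altman/Wilcoxon) or 3 subjects
(correlations) raise; B1 outside (0.5, 1.5], non-positive relaxation times,
pH shifts outside the calibration interval, and empty/duplicate basis sets
raise. Ties in "tallest peak" selection resolve to the global maximum of
the resampled model curve. Seeded `numpy.random.default_rng` streams make
every stochastic path reproducible; scene generation is bit-deterministic
for a fixed seed.

## Problem sizes

The test and acceptance runs use 4×4–8×8 CSI grids, 40–200 Monte-Carlo
replicates per calibration claim, 1024-point spectra (65 536 points only
for the 0.03 Hz-resolution splitting measurements), and 5-replicate means
for the ³¹P ratio recoveries — sizes chosen so the full suite documents the
pipeline's statistical behavior in about a minute of CPU.
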