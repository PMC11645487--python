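# ketospec

Simulation and quantification pipeline for detecting **ketone bodies**
(β-hydroxybutyrate, acetoacetate, acetone) and lactate in **¹H/³¹P MR
spectroscopic imaging of brain tumors** at 3 T.

Fasting and ketogenic interventions raise circulating ketone bodies, which
accumulate preferentially in glioma tissue. Detecting them in vivo is hard:
the β-OHB methyl doublet (1.19 ppm, J = 6.3 Hz) sits next to lactate
(1.31 ppm, J = 7 Hz) on top of lipid signals. At a long echo time the
J-coupled doublets invert — lactate fully at TE = 1/J ≈ 144 ms, β-OHB near
160 ms — while short-T₂ lipids decay away, making both metabolites
separable. Conventional PRESS localization corrupts this J-modulation
through the chemical-shift displacement error (CSDE); sLASER's
high-bandwidth adiabatic refocusing preserves it.

`ketospec` implements that entire analysis chain on ground-truth-known
synthetic data:

| module | what it does |
| --- | --- |
| `ketospec.spin_sim` | density-matrix simulation of J-coupled spin systems under ideal spin-echo / sLASER / CSDE-afflicted PRESS at arbitrary TE; basis-set export |
| `ketospec.systems` | preset chemical shifts / J-couplings for the ketone bodies, lactate and the standard brain metabolites |
| `ketospec.synthetic_data` | two-session (baseline / post-fasting) ¹H CSI generation with tumor compartments, water reference, B1 map; ³¹P FID CSI; bottle phantom; segmentation masks |
| `ketospec.lc_fitting` | LCModel-style linear-combination fitting (variable projection, non-negative amplitudes, spline baseline) with Cramér–Rao bounds and quality-gate rejection |
| `ketospec.p31_fitting` | AMARES-style 15-component time-domain ³¹P fitting; intracellular pH from the Pi shift; PME/PDE and ATP/PCr ratios |
| `ketospec.quantification` | absolute concentrations (mM) by internal water referencing with T₁/T₂ and B1 corrections |
| `ketospec.repeatability_stats` | paired Wilcoxon (exact), Bland–Altman, coefficient of variation, Spearman ρ (exact permutation), ketone-body-vs-tumor-volume correlations |

The two fitters are scikit-learn-style estimators
(`LinearCombinationModel`, `AmaresModel`: `fit`, fitted `_`-suffixed
attributes, `get_params`/`set_params`); the module-level functions
(`fit_spectrum`, `fit_amares`, …) are thin wrappers around them.

## The model in brief

A metabolite is a set of proton groups with shifts δ (ppm) and scalar
couplings J (Hz). The engine evolves ρ through
90° – (delays + refocusing π pulses) – echo under
H = Σᵢ 2π νᵢ Iᵢz + Σᵢ<ⱼ 2π Jᵢⱼ Iᵢ·Iⱼ with ideal instantaneous pulses and no
relaxation, and reads out lines (frequency, complex amplitude) at the echo
top. For a weakly coupled doublet the integrated amplitude follows
`N · cos(π J TE)` — the engine reproduces this to 10⁻⁶ in the weak-coupling
limit and adds the genuine second-order corrections at 3 T field strength.

PRESS CSDE: each coupling partner's refocusing slabs are displaced relative
to the observed group's voxel by `Δf/BW` per direction; the voxel is
partitioned into sub-regions with constant refocusing patterns, each evolved
exactly with group-selective π pulses, and crusher-style coherence selection
retains only groups refocused by both pulses.

Fitting solves `min ‖Re[e^{-iφ}S(f)] − Σₘ aₘ Bₘ(f − Δf; w + d) − spline(f)‖²`
with aₘ ≥ 0 (variable projection over global shift Δf, phase φ, damping d);
CRLB% = 100·√[F⁻¹]ₘₘ/aₘ with Fisher matrix F from the full Jacobian and the
noise variance estimated at 9–10 ppm. Absolute quantification:
`C = (Sₘ/S_w)·(2/Nₘ)·55510 mM·water_content·(R_w/Rₘ)` with
`R = e^{-TE/T₂}(1 − e^{-TR/T₁})`.

## Worked example

```python
import numpy as np
import ketospec as ks
from ketospec.systems import get_system, DEFAULT_BASIS_NAMES
from ketospec.synthetic_data import make_scene, render_csi, LABEL_CODES

seq = ks.SequenceSpec(kind="slaser", te=144.0)

# TE dependence of the beta-OHB doublet (T2 neglected)
for te, _, amp in ks.sweep_te(get_system("bhb"), seq, [140, 150, 159, 160, 170]):
    print(f"TE {te:5.0f} ms   beta-OHB doublet amplitude {amp/3:+.4f}")

# post-fasting session: render, fit, quantify one necrotic-core voxel
basis = ks.build_basis([get_system(n) for n in DEFAULT_BASIS_NAMES], seq)
scene = ks.make_scene(seed=7, session="S2", grid_dims=(8, 8), radii=(1.2, 2.0, 3.0))
session = render_csi(scene, basis, seed=7)
vox = tuple(np.argwhere(scene.labels == LABEL_CODES["necrotic_core"])[0])
fit = ks.fit_spectrum(session.voxel(*vox), basis)
quant = ks.quantify_session(session, {vox: fit}, basis)
```

Output:

```
TE   140 ms   beta-OHB doublet amplitude -0.9352
TE   150 ms   beta-OHB doublet amplitude -0.9830
TE   159 ms   beta-OHB doublet amplitude -0.9998
TE   160 ms   beta-OHB doublet amplitude -0.9996
TE   170 ms   beta-OHB doublet amplitude -0.9746
necrotic-core voxel: SNR 31.5, FWHM 5.7 Hz
  lac    5.30 mM  CRLB   8.1%  accepted
  bhb    0.95 mM  CRLB  31.7%  accepted
  acac   0.27 mM  CRLB  56.7%  accepted
  ace    0.00 mM  CRLB   inf%  rejected:not_detected
```

The doublet amplitude is the signed integral relative to TE → 0: −1.0 is
full inversion, reached near 159 ms for β-OHB (1/J = 1/6.3 Hz). In the
fitted voxel, lactate and β-OHB are recovered with uncertainties below their
rejection gates (40% and 80%), acetoacetate is accepted at 57% uncertainty,
and acetone — absent at this simulated concentration and noise — is
correctly flagged as not detected.

A thin CLI mirrors the common tasks:

```bash
ketospec simulate-basis --te 144 --sequence slaser --metabolites lac,bhb,acac,ace --out basis.h5
ketospec sweep-te --system bhb --from 100 --to 200 --step 1
ketospec generate-session --session S2 --seed 7 --out session.h5
ketospec fit-1h session.h5 --basis basis.h5 --out fits.csv
```

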