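"""Ground-truth-known synthetic phantoms, CSI sessions, 31P data and masks.

The generator emulates the acquisitions of a two-session (baseline / after a
72-hour fast) brain-tumor MRSI protocol at 3 T:

* a 2D 1H sLASER CSI at TE 144 ms (nominal 20x20 grid over 240x240 mm^2,
  6x6x12 mm^3 voxels, 2000 Hz bandwidth, 1024 points),
* a low-flip-angle unsuppressed water-reference CSI and a smooth B1 map,
* 31P FID CSI spectra built from the 15-component prior-knowledge model,
* a four-metabolite bottle phantom (5 mM lactate and beta-hydroxybutyrate
  plus acetoacetate and acetone) under sLASER and PRESS at several TEs,
* three-class tumor segmentation masks (edema, necrotic/non-enhancing core,
  contrast-enhancing tumor).

Scenes are deterministic for a fixed seed.  The second session keeps the
geometry and baseline concentrations of the first and only adds ketone
bodies, whose tumor concentration scales linearly with the necrotic-core
volume — the structural assumption behind the downstream correlation
analysis between ketone-body accumulation and tumor sub-region volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import p31_fitting
from .quantification import RelaxationTable, WATER_PROTON_PAIR_MOLARITY, \
    gre_steady_state, relaxation_factor
from .spin_sim import (
    BasisSet, SequenceSpec, SpectrumRecord, _complex_gaussian, render_lines,
    simulate_lines, simulate_press_csde,
)
from .systems import KETONE_BODIES, get_system

__all__ = [
    "SceneTruth",
    "CsiSession",
    "SegMask",
    "make_scene",
    "make_cohort",
    "render_csi",
    "render_phantom",
    "render_p31",
    "make_masks",
    "LABEL_CODES",
    "DEFAULT_CONCENTRATIONS",
]

LABEL_CODES = {"nawm": 0, "edema": 1, "necrotic_core": 2, "ce_tumor": 3}

#: baseline (session 1) concentrations in mM per tissue compartment
DEFAULT_CONCENTRATIONS = {
    "nawm": {"naa": 10.0, "cr": 7.5, "cho": 1.57, "mi": 5.0, "glx": 8.0,
             "lac": 1.80},
    "edema": {"naa": 8.0, "cr": 7.0, "cho": 1.70, "mi": 6.0, "glx": 7.0,
              "lac": 3.00},
    "ce_tumor": {"naa": 5.0, "cr": 5.5, "cho": 1.90, "mi": 6.0, "glx": 7.0,
                 "lac": 4.92},
    "necrotic_core": {"naa": 2.0, "cr": 3.0, "cho": 1.90, "mi": 4.0,
                      "glx": 5.0, "lac": 4.92},
}

#: ketone-body concentration per mL of necrotic-core volume (session 2)
KB_SLOPE_MM_PER_ML = 0.35
KB_RATIOS = {"bhb": 1.0, "acac": 0.5, "ace": 0.25}

DEFAULT_FWHM_HZ = 5.7  # canonical in-vivo linewidth
#: frequency-domain real-part noise sd (a.u.); calibrated so the fitted
#: NAWM Cramér–Rao bounds land at the protocol-typical single-digit values
DEFAULT_NOISE_SIGMA = 0.022


@dataclass
class SceneTruth:
    """Ground truth for one synthetic patient session."""

    grid_dims: tuple
    labels: np.ndarray  # int codes per LABEL_CODES
    concentrations: dict  # metabolite -> 2D map in mM
    compartments: dict  # label -> metabolite -> mM
    voxel_size: tuple = (6.0, 6.0, 12.0)  # mm
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    fwhm: dict = field(default_factory=dict)  # label -> Hz
    baseline_amplitude: float = 0.3  # 3-4 ppm hump peak height, a.u.
    session: str = "S1"
    seed: int = 0

    def __post_init__(self):
        if self.session not in ("S1", "S2"):
            raise ValueError("session must be 'S1' or 'S2'")
        for met, m in self.concentrations.items():
            if np.any(np.asarray(m) < 0):
                raise ValueError(f"negative concentration map for {met}")

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def compartment_volume_ml(self, label: str) -> float:
        code = LABEL_CODES[label]
        return int(np.sum(self.labels == code)) * self.voxel_volume_ml()


@dataclass
class CsiSession:
    """One CSI acquisition: spectra grid + water reference + B1 map."""

    spectra: np.ndarray  # (ny, nx, n_points) complex
    bandwidth: float
    ppm_reference: float
    transmitter_freq: float
    domain: str
    nucleus: str
    water_reference: np.ndarray = None
    b1_map: np.ndarray = None
    seq: SequenceSpec = None
    truth: SceneTruth = None
    label: str = "S1"

    def __post_init__(self):
        if self.b1_map is not None:
            if np.any((self.b1_map <= 0.5) | (self.b1_map > 1.5)):
                raise ValueError("B1 map values must lie in (0.5, 1.5]")
        if self.water_reference is not None and np.any(self.water_reference <= 0):
            raise ValueError("water reference must be positive")

    def voxel(self, row, col) -> SpectrumRecord:
        return SpectrumRecord(
            self.spectra[row, col], bandwidth=self.bandwidth,
            ppm_reference=self.ppm_reference, domain=self.domain,
            nucleus=self.nucleus, transmitter_freq=self.transmitter_freq,
        )


@dataclass
class SegMask:
    """Integer segmentation labels: 0 background, 1 edema, 2 necrotic core,
    3 contrast-enhancing tumor."""

    labels: np.ndarray
    voxel_size: tuple = (6.0, 6.0, 12.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")

    def volume_ml(self, label_code: int) -> float:
        n = int(np.sum(self.labels == label_code))
        return n * float(np.prod(self.voxel_size)) / 1000.0

    def volumes(self) -> dict:
        return {name: self.volume_ml(code) for name, code in
                [("edema", 1), ("necrotic_core", 2), ("ce_tumor", 3)]}


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _ellipse_mask(grid_dims, center, radius):
    ny, nx = grid_dims
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius ** 2


def make_scene(
    config: dict | None = None,
    seed: int = 0,
    session: str = "S1",
    grid_dims: tuple = (20, 20),
    voxel_size: tuple = (6.0, 6.0, 12.0),
    tumor_center: tuple | None = None,
    radii: tuple | None = (2.0, 3.5, 5.5),
    kb_slope: float = KB_SLOPE_MM_PER_ML,
    kb_noise_frac: float = 0.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    fwhm_hz: float = DEFAULT_FWHM_HZ,
    baseline_amplitude: float = 0.3,
) -> SceneTruth:
    """Build a ground-truth scene with nested tumor compartments.

    ``radii`` gives the necrotic-core / contrast-enhancing / edema radii in
    voxels (nested discs); ``radii=None`` produces a tumor-free scene.  For
    session "S2" the ketone bodies are added to the necrotic core and the
    contrast-enhancing rim at ``kb_slope`` mM per mL of necrotic-core
    volume, optionally perturbed by a relative Gaussian jitter
    (``kb_noise_frac``) drawn from the scene seed.
    """
    rng = np.random.default_rng(seed)
    ny, nx = grid_dims
    labels = np.zeros(grid_dims, dtype=int)
    if radii is not None:
        if tumor_center is None:
            tumor_center = (ny * 0.5, nx * 0.65)
        r_nec, r_ce, r_ed = radii
        if not (r_nec <= r_ce <= r_ed):
            raise ValueError("radii must be nested: necrotic <= CE <= edema")
        labels[_ellipse_mask(grid_dims, tumor_center, r_ed)] = LABEL_CODES["edema"]
        labels[_ellipse_mask(grid_dims, tumor_center, r_ce)] = LABEL_CODES["ce_tumor"]
        labels[_ellipse_mask(grid_dims, tumor_center, r_nec)] = \
            LABEL_CODES["necrotic_core"]

    compartments = {k: dict(v) for k, v in DEFAULT_CONCENTRATIONS.items()}
    if config:
        for label, overrides in config.items():
            compartments.setdefault(label, {}).update(overrides)

    voxel_ml = float(np.prod(voxel_size)) / 1000.0
    if session == "S2":
        nec_ml = int(np.sum(labels == LABEL_CODES["necrotic_core"])) * voxel_ml
        base_kb = kb_slope * nec_ml
        jitter = 1.0 + kb_noise_frac * rng.standard_normal()
        for kb, ratio in KB_RATIOS.items():
            level = max(base_kb * ratio * jitter, 0.0)
            compartments["necrotic_core"].setdefault(kb, level)
            compartments["ce_tumor"].setdefault(kb, level)

    mets = sorted({m for comp in compartments.values() for m in comp})
    concentrations = {}
    for met in mets:
        m = np.zeros(grid_dims)
        for label, code in LABEL_CODES.items():
            m[labels == code] = compartments.get(label, {}).get(met, 0.0)
        concentrations[met] = m

    return SceneTruth(
        grid_dims=grid_dims, labels=labels, concentrations=concentrations,
        compartments=compartments, voxel_size=voxel_size,
        noise_sigma=noise_sigma,
        fwhm={k: fwhm_hz for k in LABEL_CODES},
        baseline_amplitude=baseline_amplitude, session=session, seed=seed,
    )


def make_cohort(n_subjects: int, seed: int = 0, session: str = "S2",
                grid_dims: tuple = (20, 20), kb_noise_frac: float = 0.10,
                **kwargs) -> list:
    """Scenes for a cohort with varying necrotic-core volumes.

    Necrotic radii are drawn uniformly between 1.2 and 3.2 voxels (scaled to
    the grid) so ketone-body levels span a range proportional to volume, with
    the configured relative jitter — the structure probed by the
    volume-correlation analysis.
    """
    rng = np.random.default_rng(seed)
    scale = grid_dims[0] / 20.0
    scenes = []
    for i in range(n_subjects):
        r_nec = rng.uniform(1.2, 3.2) * scale
        radii = (r_nec, r_nec + 1.5 * scale, r_nec + 3.5 * scale)
        scenes.append(
            make_scene(seed=int(rng.integers(2 ** 31)), session=session,
                       grid_dims=grid_dims, radii=radii,
                       kb_noise_frac=kb_noise_frac, **kwargs)
        )
    return scenes


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _default_b1_map(grid_dims):
    ny, nx = grid_dims
    yy, xx = np.mgrid[0:ny, 0:nx]
    # smooth center-bright transmit profile, ~0.9-1.1
    r2 = ((yy - ny / 2) / ny) ** 2 + ((xx - nx / 2) / nx) ** 2
    return 1.1 - 0.4 * r2


def _adjacent_to(labels, code):
    """Voxels with the given label or 8-adjacent to it."""
    m = labels == code
    out = m.copy()
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out |= np.roll(np.roll(m, dy, axis=0), dx, axis=1)
    return out


def render_csi(
    truth: SceneTruth,
    basis: BasisSet,
    seed: int | None = None,
    relax: RelaxationTable | None = None,
    tr: float = 2000.0,
    water_flip_deg: float = 2.0,
    water_tr: float = 200.0,
    water_te: float = 2.3,
    b1_map: np.ndarray | None = None,
) -> CsiSession:
    """Render a 1H CSI session from ground truth and a simulated basis.

    Per voxel the noiseless spectrum is the linear combination
    ``sum_m C_m * R_m * N_m * basis_m`` (per-proton-normalized basis entries,
    saturation/T2 relaxation factors from the quantification module) rendered
    at the compartment linewidth, plus a broad baseline hump in the 3-4 ppm
    band for voxels adjacent to necrosis, plus circular complex Gaussian
    noise generated in the time domain.  The water reference is the
    compartment water content times the proton-pair molarity of water, seen
    through the low-flip gradient-echo steady state with the B1-scaled flip
    angle.
    """
    seq = basis.seq or SequenceSpec()
    if abs(basis.te - seq.te) > 1e-9:
        raise ValueError("basis TE does not match sequence TE")
    relax = relax or RelaxationTable()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    grid = basis.grid()
    n_points, bw = grid.n_points, grid.bandwidth
    f0 = grid.transmitter_freq
    faxis = grid.freq_axis()

    # relaxation factor per metabolite at the spectroscopy TR/TE
    r_met = {}
    for met in basis.names:
        t1, t2 = relax.times(met)
        r_met[met] = relaxation_factor(tr, basis.te, t1, t2)

    # per-compartment unit spectra per metabolite (rendered once per label)
    unit = {}
    for label, code in LABEL_CODES.items():
        fw = truth.fwhm.get(label, DEFAULT_FWHM_HZ)
        mat = np.empty((len(basis.names), n_points), dtype=complex)
        for i, met in enumerate(basis.names):
            freqs, amps = basis.lines[met]
            mat[i] = render_lines(
                freqs, amps, n_points=n_points, bandwidth=bw,
                ppm_reference=grid.ppm_reference, transmitter_freq=f0,
                lineshape=("lorentzian", fw),
            ).complex_points
        unit[code] = mat

    hump_f0 = (3.5 - grid.ppm_reference) * f0
    hump_fwhm = 0.5 * f0  # 0.5 ppm wide
    hump = _complex_gaussian(faxis - hump_f0, hump_fwhm)
    hump = hump / np.max(hump.real)  # unit peak height
    near_necrosis = _adjacent_to(truth.labels, LABEL_CODES["necrotic_core"])

    ny, nx = truth.grid_dims
    spectra = np.zeros((ny, nx, n_points), dtype=complex)
    conc = np.array([[truth.concentrations.get(met, np.zeros(truth.grid_dims))
                      for met in basis.names]])[0]
    scale = np.array([r_met[met] * basis.n_protons[met] for met in basis.names])

    sigma_t = truth.noise_sigma * bw / np.sqrt(n_points)
    for r in range(ny):
        for c in range(nx):
            code = int(truth.labels[r, c])
            coeff = conc[:, r, c] * scale
            spec = coeff @ unit[code]
            if truth.baseline_amplitude and near_necrosis[r, c]:
                spec = spec + truth.baseline_amplitude * hump
            if truth.noise_sigma > 0:
                noise_t = sigma_t * (
                    rng.standard_normal(n_points)
                    + 1j * rng.standard_normal(n_points)
                )
                spec = spec + np.fft.fftshift(np.fft.fft(noise_t)) / bw
            spectra[r, c] = spec

    b1 = _default_b1_map(truth.grid_dims) if b1_map is None else b1_map
    wc_by_code = {LABEL_CODES[k]: v for k, v in relax.water_content.items()}
    water = np.zeros((ny, nx))
    for code, wc in wc_by_code.items():
        # raw water signal: 2 protons per molecule at 55.51 M, T2* decayed
        m0 = wc * 2.0 * WATER_PROTON_PAIR_MOLARITY * np.exp(
            -water_te / relax.water_t2)
        sel = truth.labels == code
        water[sel] = m0
    water = water * gre_steady_state(np.deg2rad(water_flip_deg) * b1,
                                     water_tr, relax.water_t1)

    return CsiSession(
        spectra=spectra, bandwidth=bw, ppm_reference=grid.ppm_reference,
        transmitter_freq=f0, domain="frequency", nucleus="1H",
        water_reference=water, b1_map=b1, seq=seq, truth=truth,
        label=truth.session,
    )


PHANTOM_TE_LIST = (40.0, 80.0, 120.0, 144.0, 288.0)
PHANTOM_CONCENTRATION_MM = 5.0


def render_phantom(basis_seq: SequenceSpec | None = None, te_list=None,
                   fwhm_hz: float = 2.0, press_bandwidth: float = 1300.0):
    """Single-compartment bottle-phantom spectra at several TEs.

    The phantom holds 5 mM lactate, beta-hydroxybutyrate, acetoacetate and
    acetone.  Returns a list of ``(mode, te, SpectrumRecord)`` for both the
    ideal-refocusing sLASER mode and the displacement-afflicted PRESS mode.
    """
    te_list = PHANTOM_TE_LIST if te_list is None else tuple(te_list)
    base = basis_seq or SequenceSpec(kind="slaser", te=144.0)
    systems = [get_system(n) for n in ("lac", "bhb", "acac", "ace")]
    out = []
    for te in te_list:
        for mode in ("slaser", "press"):
            if mode == "slaser":
                seq = SequenceSpec(kind="slaser", te=te, carrier=base.carrier,
                                   transmitter_freq=base.transmitter_freq)
                sim = lambda s: simulate_lines(s, seq)  # noqa: E731
            else:
                seq = SequenceSpec(kind="press", te=te, carrier=base.carrier,
                                   transmitter_freq=base.transmitter_freq,
                                   refocus_bandwidth=press_bandwidth)
                sim = lambda s: simulate_press_csde(s, seq, return_lines=True)  # noqa: E731
            freqs_all, amps_all = [], []
            for sys_ in systems:
                f, a = sim(sys_)
                freqs_all.append(f)
                amps_all.append(PHANTOM_CONCENTRATION_MM * a)
            rec = render_lines(
                np.concatenate(freqs_all), np.concatenate(amps_all),
                n_points=4096, bandwidth=2000.0, ppm_reference=base.carrier,
                transmitter_freq=base.transmitter_freq,
                lineshape=("lorentzian", fwhm_hz),
            )
            out.append((mode, float(te), rec))
    return out


#: per-sample time-domain complex-noise sd of the 31P CSI (protocol-like:
#: PCr amplitude-relative Cramér–Rao SD around 2%)
DEFAULT_P31_NOISE_SIGMA = 0.08


def render_p31(truth: SceneTruth, seed: int | None = None,
               n_points: int = 1024, bandwidth: float = 2000.0,
               noise_sigma: float = DEFAULT_P31_NOISE_SIGMA) -> CsiSession:
    """31P FID CSI of the scene from the 15-component model presets.

    Tumor compartments (necrotic core, contrast-enhancing, edema) use the
    tumor preset (pH 7.08, PME/PDE 0.71, ATP/PCr 0.69); normal-appearing
    white matter uses the NAWM preset (pH 7.03, PME/PDE 0.51, ATP/PCr 0.67).
    ``noise_sigma`` is the per-sample time-domain sd of the complex noise.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    presets = p31_fitting.P31_COMPARTMENT_PRESETS
    fid_by_code = {}
    for label, code in LABEL_CODES.items():
        key = "nawm" if label == "nawm" else "tumor"
        model = p31_fitting.default_p31_model(**presets[key])
        fid_by_code[code] = p31_fitting.synthesize_fid(
            model, n_points=n_points, bandwidth=bandwidth)
    ny, nx = truth.grid_dims
    spectra = np.zeros((ny, nx, n_points), dtype=complex)
    for r in range(ny):
        for c in range(nx):
            fid = fid_by_code[int(truth.labels[r, c])]
            if noise_sigma > 0:
                fid = fid + noise_sigma * (
                    rng.standard_normal(n_points)
                    + 1j * rng.standard_normal(n_points)
                )
            spectra[r, c] = fid
    return CsiSession(
        spectra=spectra, bandwidth=bandwidth, ppm_reference=0.0,
        transmitter_freq=p31_fitting.P31_TRANSMITTER_MHZ, domain="time",
        nucleus="31P", water_reference=None, b1_map=None, seq=None,
        truth=truth, label=truth.session,
    )


def make_masks(truth: SceneTruth) -> SegMask:
    """Export the scene's tumor labels as a three-class segmentation mask."""
    return SegMask(labels=truth.labels.copy(), voxel_size=truth.voxel_size)
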