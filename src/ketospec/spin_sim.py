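"""Density-matrix simulation of J-coupled spin systems under spin-echo localization.

The engine evolves the full Hilbert-space density matrix of a small proton
spin system through an idealized localization sequence (ideal spin echo,
sLASER with four refocusing pulses, or PRESS with two) and reads out the
transverse magnetization at the echo top as a list of spectral lines
(frequency, complex amplitude).  Radiofrequency pulses are instantaneous
rotations; relaxation during the sequence is neglected, so any TE dependence
of multiplet amplitudes is purely J-modulation.

Conventions
-----------
* The rotating frame is set by ``SequenceSpec.carrier`` (ppm); line
  frequencies are offsets in Hz from the carrier.
* Amplitudes are normalized so that an uncoupled group of *n* protons at
  unit concentration integrates to *n* at TE -> 0.
* Refocusing pulses rotate about +y, so an ideal echo returns in-phase
  magnetization with positive absorption lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpinSystem",
    "SequenceSpec",
    "SpectrumRecord",
    "BasisSet",
    "CapacityError",
    "simulate_sequence",
    "simulate_lines",
    "sweep_te",
    "target_group_ppm",
    "simulate_press_csde",
    "build_basis",
    "doublet_amplitude",
    "render_lines",
    "lines_to_fid",
]

MAX_SPINS = 8  # Hilbert-space cap: 2**8 = 256
MAX_GROUPS = 6

DEFAULT_TRANSMITTER_MHZ = 127.73  # nominal 3 T proton frequency
WATER_PPM = 4.70


class CapacityError(ValueError):
    """Spin system exceeds the configured Hilbert-space capacity."""


@dataclass(frozen=True)
class SpinSystem:
    """A metabolite spin system: chemically shifted groups of equivalent protons.

    Parameters
    ----------
    name : str
        Metabolite identifier (lower-case short name, e.g. ``"lac"``).
    groups : tuple of (float, int)
        ``(chemical_shift_ppm, n_protons)`` per magnetically equivalent group.
    couplings : ndarray, shape (G, G)
        Symmetric scalar-coupling matrix in Hz between groups, zero diagonal.
    """

    name: str
    groups: tuple
    couplings: np.ndarray = None

    def __post_init__(self):
        groups = tuple((float(s), int(n)) for s, n in self.groups)
        object.__setattr__(self, "groups", groups)
        G = len(groups)
        if G == 0:
            raise ValueError("spin system needs at least one group")
        if G > MAX_GROUPS:
            raise CapacityError(f"{G} groups exceed the cap of {MAX_GROUPS}")
        J = self.couplings
        if J is None:
            J = np.zeros((G, G))
        J = np.asarray(J, dtype=float)
        if J.shape != (G, G):
            raise ValueError(f"couplings must be {G}x{G}")
        if not np.allclose(J, J.T):
            raise ValueError("couplings must be symmetric")
        if np.any(np.diag(J) != 0):
            raise ValueError("couplings must have zero diagonal")
        object.__setattr__(self, "couplings", J)
        for shift, n in groups:
            if n < 1:
                raise ValueError("each group needs n_protons >= 1")
            if not (0.0 <= shift <= 10.0):
                raise ValueError(f"shift {shift} ppm outside 0-10 ppm")

    @property
    def n_protons(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass(frozen=True)
class SequenceSpec:
    """Localization-sequence timing and hardware parameters."""

    kind: str = "slaser"  # ideal_se | slaser | press
    te: float = 144.0  # ms
    sub_echo_fractions: tuple = None
    refocus_bandwidth: float = 5000.0  # Hz per refocusing pulse
    carrier: float = WATER_PPM  # ppm
    transmitter_freq: float = DEFAULT_TRANSMITTER_MHZ  # MHz
    slice_thickness_factor: float = 1.0

    def __post_init__(self):
        if self.kind not in ("ideal_se", "slaser", "press"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if self.te <= 0:
            raise ValueError("TE must be > 0")
        if self.refocus_bandwidth <= 0:
            raise ValueError("refocus bandwidth must be > 0")
        fr = self.sub_echo_fractions
        if fr is None:
            if self.kind == "ideal_se":
                fr = (1.0,)
            elif self.kind == "slaser":
                fr = (0.25, 0.25, 0.25, 0.25)
            else:  # press: short first echo, as on clinical systems
                fr = (0.2, 0.8)
        fr = tuple(float(f) for f in fr)
        if any(f <= 0 for f in fr):
            raise ValueError("sub-echo fractions must be positive")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("sub-echo fractions must sum to 1")
        object.__setattr__(self, "sub_echo_fractions", fr)

    @property
    def n_refocus(self) -> int:
        return len(self.sub_echo_fractions)

    def pulse_times(self):
        """Refocusing-pulse instants (ms): centered within each sub-echo."""
        te = self.te
        edges = np.concatenate([[0.0], np.cumsum(self.sub_echo_fractions)]) * te
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class SpectrumRecord:
    """A complex spectrum or FID with axis metadata."""

    complex_points: np.ndarray
    bandwidth: float  # Hz
    ppm_reference: float = WATER_PPM  # ppm at zero frequency offset
    domain: str = "frequency"  # time | frequency
    nucleus: str = "1H"
    transmitter_freq: float = DEFAULT_TRANSMITTER_MHZ  # MHz

    def __post_init__(self):
        self.complex_points = np.asarray(self.complex_points, dtype=complex)
        if self.domain not in ("time", "frequency"):
            raise ValueError("domain must be 'time' or 'frequency'")
        if self.nucleus not in ("1H", "31P"):
            raise ValueError("nucleus must be '1H' or '31P'")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    @property
    def n_points(self) -> int:
        return self.complex_points.size

    def freq_axis(self) -> np.ndarray:
        """Frequency offsets (Hz) from the carrier, increasing."""
        n, bw = self.n_points, self.bandwidth
        return -bw / 2 + bw * np.arange(n) / n

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis (ppm), increasing with index."""
        return self.ppm_reference + self.freq_axis() / self.transmitter_freq

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) / self.bandwidth


@dataclass
class BasisSet:
    """Simulated metabolite basis for linear-combination fitting.

    ``entries`` hold rendered frequency-domain spectra per metabolite at unit
    (1 mM) concentration with per-proton normalization: the line amplitudes of
    each metabolite are divided by its total proton count, so every entry
    integrates to 1 at TE -> 0.  ``lines`` keep the underlying (freqs, amps)
    line lists so fitters and generators can re-render at any linewidth.
    """

    te: float
    entries: dict
    lineshape: tuple = ("lorentzian", 1.0)  # (model, fwhm Hz)
    lines: dict = field(default_factory=dict)
    n_protons: dict = field(default_factory=dict)
    seq: SequenceSpec = None

    def __post_init__(self):
        if not self.entries:
            raise ValueError("basis set must not be empty")
        meta = None
        for name, rec in self.entries.items():
            key = (rec.n_points, rec.bandwidth, rec.ppm_reference, rec.nucleus)
            if meta is None:
                meta = key
            elif key != meta:
                raise ValueError("basis entries must share axis metadata")

    @property
    def names(self):
        return list(self.entries)

    def grid(self) -> SpectrumRecord:
        return next(iter(self.entries.values()))


# ---------------------------------------------------------------------------
# Hilbert-space machinery
# ---------------------------------------------------------------------------

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
_ID = np.eye(2, dtype=complex)


def _kron_chain(ops):
    out = ops[0]
    for op in ops[1:]:
        out = np.kron(out, op)
    return out


def _single_spin_ops(n_spins, base):
    return [
        _kron_chain([base if j == i else _ID for j in range(n_spins)])
        for i in range(n_spins)
    ]


def _rot_y(theta):
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _rot_x(theta):
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)


class _Engine:
    """Dense density-matrix evolution for one spin system in one frame."""

    def __init__(self, system: SpinSystem, seq: SequenceSpec, max_spins: int = MAX_SPINS):
        self.system = system
        self.seq = seq
        spin_group = []
        for g, (_, n) in enumerate(system.groups):
            spin_group.extend([g] * n)
        self.spin_group = spin_group
        n_spins = len(spin_group)
        if n_spins > max_spins:
            raise CapacityError(
                f"{system.name}: {n_spins} spins exceed the cap of {max_spins}"
            )
        self.n_spins = n_spins
        self.dim = 2 ** n_spins
        f0 = seq.transmitter_freq  # MHz: Hz per ppm
        self.offsets_hz = np.array(
            [(system.groups[g][0] - seq.carrier) * f0 for g in spin_group]
        )
        Ix = _single_spin_ops(n_spins, _SX)
        Iy = _single_spin_ops(n_spins, _SY)
        Iz = _single_spin_ops(n_spins, _SZ)
        H = np.zeros((self.dim, self.dim), dtype=complex)
        for i in range(n_spins):
            H += 2 * np.pi * self.offsets_hz[i] * Iz[i]
        J = system.couplings
        for i in range(n_spins):
            for j in range(i + 1, n_spins):
                gi, gj = spin_group[i], spin_group[j]
                if gi == gj:
                    continue  # intra-group coupling between equivalent spins is spectrally silent
                Jij = J[gi, gj]
                if Jij == 0.0:
                    continue
                H += (
                    2 * np.pi * Jij
                    * (Ix[i] @ Ix[j] + Iy[i] @ Iy[j] + Iz[i] @ Iz[j])
                )
        # H is in rad/ms once delays are given in ms; keep rad/s and convert delays.
        self.evals, self.evecs = np.linalg.eigh(H)
        self.Iz_tot = sum(Iz)
        self.Iplus = [Ix[i] + 1j * Iy[i] for i in range(n_spins)]

    def _pulse_op(self, rot2, spins):
        return _kron_chain([rot2 if i in spins else _ID for i in range(self.n_spins)])

    def run(self, flips_per_pulse=None, detect_groups=None):
        """Evolve through the echo and return spectral lines at the echo top.

        Parameters
        ----------
        flips_per_pulse : list of set of group index, optional
            Which groups each refocusing pulse inverts.  Default: all groups
            for every pulse (ideal, CSDE-free refocusing).
        detect_groups : set of group index, optional
            Groups whose transverse signal survives coherence selection.
            Default: all groups.

        Returns
        -------
        freqs, amps : ndarray
            Line frequencies (Hz offset from carrier) and complex amplitudes.
        """
        seq = self.seq
        n_groups = len(self.system.groups)
        all_groups = set(range(n_groups))
        pulse_times = seq.pulse_times()
        if flips_per_pulse is None:
            flips_per_pulse = [all_groups] * len(pulse_times)
        if detect_groups is None:
            detect_groups = all_groups

        rho = self.Iz_tot.copy()
        R90 = self._pulse_op(_rot_x(np.pi / 2), set(range(self.n_spins)))
        rho = R90 @ rho @ R90.conj().T

        te_s = seq.te * 1e-3
        times = np.concatenate([[0.0], np.asarray(pulse_times) * 1e-3, [te_s]])
        V, E = self.evecs, self.evals
        for k, flips in enumerate(flips_per_pulse):
            rho = self._delay(rho, times[k + 1] - times[k])
            spins = {i for i in range(self.n_spins) if self.spin_group[i] in flips}
            if spins:
                P = self._pulse_op(_rot_y(np.pi), spins)
                rho = P @ rho @ P.conj().T
        rho = self._delay(rho, times[-1] - times[-2])

        D = sum(
            self.Iplus[i]
            for i in range(self.n_spins)
            if self.spin_group[i] in detect_groups
        )
        if np.isscalar(D):  # no detected spins
            return np.array([]), np.array([])
        rho_t = V.conj().T @ rho @ V
        D_t = V.conj().T @ D @ V
        # s(t) = Tr(rho(t) D) = sum_jk rho~_jk D~_kj exp(-i (E_j - E_k) t)
        amp = rho_t * D_t.T
        scale = 1j * 2.0 ** (2 - self.n_spins)
        freqs_all = (E[None, :] - E[:, None]) / (2 * np.pi)  # f_jk = (E_k - E_j)/2pi
        mask = np.abs(amp) > 1e-9
        freqs = freqs_all[mask]
        amps = scale * amp[mask]
        return _merge_lines(freqs, amps)

    def _delay(self, rho, dt_s):
        if dt_s <= 0:
            return rho
        V, E = self.evecs, self.evals
        phase = np.exp(-1j * E * dt_s)
        U = (V * phase) @ V.conj().T
        return U @ rho @ U.conj().T


def _merge_lines(freqs, amps, tol=1e-6):
    if freqs.size == 0:
        return freqs, amps
    order = np.argsort(freqs)
    freqs, amps = freqs[order], amps[order]
    out_f, out_a = [freqs[0]], [amps[0]]
    for f, a in zip(freqs[1:], amps[1:]):
        if f - out_f[-1] < tol:
            out_a[-1] += a
        else:
            out_f.append(f)
            out_a.append(a)
    out_f, out_a = np.array(out_f), np.array(out_a)
    keep = np.abs(out_a) > 1e-9
    return out_f[keep], out_a[keep]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _complex_lorentzian(df, fwhm):
    """Complex Lorentzian with unit real-part area; df in Hz."""
    R = np.pi * fwhm
    return 2.0 / (R + 2j * np.pi * df)


def _complex_gaussian(df, fwhm):
    """Complex Gaussian line (absorption + dispersion) with unit real area."""
    from scipy.special import wofz

    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    z = (df + 1e-12j) / (sigma * np.sqrt(2))
    return wofz(z) / (sigma * np.sqrt(2 * np.pi))


def render_lines(
    freqs,
    amps,
    n_points=1024,
    bandwidth=2000.0,
    ppm_reference=WATER_PPM,
    transmitter_freq=DEFAULT_TRANSMITTER_MHZ,
    lineshape=("lorentzian", 1.0),
    nucleus="1H",
) -> SpectrumRecord:
    """Render a line list to a frequency-domain spectrum with a given lineshape."""
    model, fwhm = lineshape
    if fwhm <= 0:
        raise ValueError("lineshape fwhm must be > 0")
    prof = {"lorentzian": _complex_lorentzian, "gaussian": _complex_gaussian}[model]
    f = -bandwidth / 2 + bandwidth * np.arange(n_points) / n_points
    spec = np.zeros(n_points, dtype=complex)
    for f0, a in zip(freqs, amps):
        spec += a * prof(f - f0, fwhm)
    return SpectrumRecord(
        spec,
        bandwidth=bandwidth,
        ppm_reference=ppm_reference,
        domain="frequency",
        nucleus=nucleus,
        transmitter_freq=transmitter_freq,
    )


def lines_to_fid(freqs, amps, n_points, bandwidth, fwhm):
    """Synthesize a Lorentzian-damped FID from a line list (consistent with
    :func:`render_lines`: the continuous FT of this FID is the rendered profile)."""
    t = np.arange(n_points) / bandwidth
    R = np.pi * fwhm
    fid = np.zeros(n_points, dtype=complex)
    for f0, a in zip(freqs, amps):
        fid += a * np.exp((2j * np.pi * f0 - R) * t)
    return fid


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _coupled_clusters(system: SpinSystem):
    """Partition group indices into J-coupled clusters (union-find)."""
    G = len(system.groups)
    parent = list(range(G))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    J = system.couplings
    for i in range(G):
        for j in range(i + 1, G):
            if J[i, j] != 0.0:
                parent[find(i)] = find(j)
    clusters = {}
    for g in range(G):
        clusters.setdefault(find(g), []).append(g)
    return list(clusters.values())


def _subsystem(system: SpinSystem, groups):
    idx = list(groups)
    return SpinSystem(
        name=system.name,
        groups=tuple(system.groups[g] for g in idx),
        couplings=system.couplings[np.ix_(idx, idx)],
    )


def simulate_lines(system: SpinSystem, seq: SequenceSpec, max_spins: int = MAX_SPINS):
    """Echo-top line list for ideal (CSDE-free) refocusing.

    J-coupled clusters are simulated independently in their own product
    spaces (line contributions are additive); an uncoupled group is a
    TE-independent singlet of amplitude equal to its proton count, since an
    ideal echo refocuses its chemical shift and there is no J evolution.
    """
    f0 = seq.transmitter_freq
    all_freqs, all_amps = [], []
    for cluster in _coupled_clusters(system):
        if len(cluster) == 1:
            shift, n = system.groups[cluster[0]]
            all_freqs.append(np.array([(shift - seq.carrier) * f0]))
            all_amps.append(np.array([complex(n)]))
        else:
            sub = _subsystem(system, cluster)
            freqs, amps = _Engine(sub, seq, max_spins=max_spins).run()
            all_freqs.append(freqs)
            all_amps.append(amps)
    return _merge_lines(np.concatenate(all_freqs), np.concatenate(all_amps))


def simulate_sequence(
    system: SpinSystem,
    seq: SequenceSpec,
    lineshape=("lorentzian", 1.0),
    n_points=4096,
    bandwidth=2000.0,
    max_spins: int = MAX_SPINS,
) -> SpectrumRecord:
    """Simulate one metabolite under ideal refocusing and render its spectrum.

    T2 decay during the sequence is neglected; all TE dependence is
    J-modulation.  For ``kind != 'press'`` the chemical-shift displacement
    error is ignored (every refocusing pulse inverts all spins); PRESS via
    this entry point is likewise the ideal two-pulse echo — displacement
    effects live in :func:`simulate_press_csde`.
    """
    freqs, amps = simulate_lines(system, seq, max_spins=max_spins)
    return render_lines(
        freqs,
        amps,
        n_points=n_points,
        bandwidth=bandwidth,
        ppm_reference=seq.carrier,
        transmitter_freq=seq.transmitter_freq,
        lineshape=lineshape,
    )


def doublet_amplitude(freqs, amps, target_ppm, seq: SequenceSpec, window_ppm=0.3):
    """Signed integrated amplitude of the multiplet nearest ``target_ppm``."""
    f0 = (target_ppm - seq.carrier) * seq.transmitter_freq
    w = window_ppm * seq.transmitter_freq
    sel = np.abs(freqs - f0) <= w
    return float(np.sum(amps[sel].real))


def target_group_ppm(system: SpinSystem) -> float:
    """Shift of the reported multiplet: the group with the most protons."""
    return max(system.groups, key=lambda g: g[1])[0]


def measure_doublet_splitting(rec: SpectrumRecord, target_ppm: float,
                              window_ppm: float = 0.12):
    """Peak-pick a rendered doublet: (splitting Hz, center ppm).

    Uses the magnitude spectrum, which keeps the peak maxima at the line
    positions regardless of the in-phase/antiphase mix at the echo top.
    The two most prominent local maxima within the window are used.
    """
    from scipy.signal import find_peaks

    f = rec.freq_axis()
    ppm = rec.ppm_axis()
    mag = np.abs(rec.complex_points)
    sel = np.abs(ppm - target_ppm) <= window_ppm
    idx = np.flatnonzero(sel)
    peaks, props = find_peaks(mag[idx], prominence=0.05 * mag[idx].max())
    if peaks.size < 2:
        raise ValueError("fewer than two peaks found in the window")
    order = np.argsort(props["prominences"])[::-1][:2]
    i1, i2 = idx[peaks[order[0]]], idx[peaks[order[1]]]
    splitting = float(abs(f[i2] - f[i1]))
    center = float(0.5 * (ppm[i1] + ppm[i2]))
    return splitting, center


def sweep_te(system: SpinSystem, seq: SequenceSpec, te_grid, render=False):
    """Simulate a TE series and report the signed target-multiplet amplitude.

    Returns a list of ``(te, SpectrumRecord or None, amplitude)`` tuples.
    """
    te_grid = list(te_grid)
    if not te_grid:
        raise ValueError("te_grid must be non-empty")
    if any(b <= a for a, b in zip(te_grid, te_grid[1:])):
        raise ValueError("te_grid must be strictly increasing")
    ppm = target_group_ppm(system)
    out = []
    for te in te_grid:
        s = replace(seq, te=float(te))
        freqs, amps = simulate_lines(system, s)
        amp = doublet_amplitude(freqs, amps, ppm, s)
        rec = None
        if render:
            rec = render_lines(
                freqs, amps, ppm_reference=s.carrier,
                transmitter_freq=s.transmitter_freq,
            )
        out.append((float(te), rec, amp))
    return out


def _partition_1d(deltas):
    """Partition the unit voxel extent by which groups a slice pulse refocuses.

    ``deltas``: per-group slice displacement as a fraction of the voxel
    extent.  Returns a list of ``(weight, refocused_group_set)``.
    """
    edges = {0.0, 1.0}
    for d in deltas:
        if d > 0:
            edges.add(min(d, 1.0))
        elif d < 0:
            edges.add(max(1.0 + d, 0.0))
    edges = sorted(edges)
    regions = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 1e-12:
            continue
        x = 0.5 * (a + b)
        inslice = frozenset(
            g for g, d in enumerate(deltas)
            if (x >= d if d >= 0 else x <= 1.0 + d)
        )
        regions.append((b - a, inslice))
    return regions


def simulate_press_csde(
    system: SpinSystem,
    seq: SequenceSpec,
    voxel_extent: float = 1.0,
    lineshape=("lorentzian", 1.0),
    n_points=4096,
    bandwidth=2000.0,
    return_lines=False,
):
    """PRESS spectrum with chemical-shift displacement along both refocusing axes.

    Each refocusing pulse selects a slice whose position depends on resonance
    frequency: group *g*'s slice is displaced by ``offset_hz(g) / bandwidth``
    voxel fractions.  The voxel is partitioned per refocusing direction into
    sub-regions with a constant set of refocused groups; each sub-region is
    evolved exactly with group-selective refocusing pulses.  Crusher-style
    coherence selection keeps, at detection, only the signal of groups
    refocused by both pulses.  As the refocusing bandwidth grows the result
    converges to the ideal :func:`simulate_sequence` spectrum.
    """
    if seq.kind != "press":
        raise ValueError("simulate_press_csde requires a PRESS sequence spec")
    if seq.refocus_bandwidth <= 0:
        raise ValueError("refocus bandwidth must be > 0")
    f0 = seq.transmitter_freq
    all_freqs, all_amps = [], []
    for cluster in _coupled_clusters(system):
        if len(cluster) == 1:
            # uncoupled singlet: its excitation and two refocusing slabs are
            # displaced along three different axes, so its own (shifted)
            # voxel is fully selected and there is no J partner to lose
            shift, n = system.groups[cluster[0]]
            all_freqs.append(np.array([(shift - seq.carrier) * f0]))
            all_amps.append(np.array([complex(n)]))
            continue
        sub = _subsystem(system, cluster)
        engine = _Engine(sub, seq)
        group_delta = {}
        for spin, g in enumerate(engine.spin_group):
            group_delta[g] = (
                engine.offsets_hz[spin]
                / seq.refocus_bandwidth
                * seq.slice_thickness_factor
            )
        n_sub = len(sub.groups)
        cache = {}
        # Each group is observed within its own fully selected voxel; the
        # COUPLING PARTNERS' refocusing slabs are displaced relative to it by
        # (offset_partner - offset_observed)/bandwidth voxel fractions per
        # refocusing direction.
        for obs in range(n_sub):
            rel = [group_delta[g] - group_delta[obs] for g in range(n_sub)]
            regions = _partition_1d(rel)
            for w1, s1 in regions:
                for w2, s2 in regions:
                    key = (obs, s1, s2)
                    if key not in cache:
                        cache[key] = engine.run(
                            flips_per_pulse=[set(s1), set(s2)],
                            detect_groups={obs},
                        )
                    freqs, amps = cache[key]
                    if freqs.size:
                        all_freqs.append(freqs)
                        all_amps.append(amps * (w1 * w2))
    if all_freqs:
        freqs = np.concatenate(all_freqs)
        amps = np.concatenate(all_amps)
        freqs, amps = _merge_lines(freqs, amps)
    else:
        freqs, amps = np.array([]), np.array([])
    if return_lines:
        return freqs, amps
    return render_lines(
        freqs,
        amps,
        n_points=n_points,
        bandwidth=bandwidth,
        ppm_reference=seq.carrier,
        transmitter_freq=seq.transmitter_freq,
        lineshape=lineshape,
    )


def build_basis(
    systems,
    seq: SequenceSpec,
    lineshape=("lorentzian", 1.0),
    n_points=1024,
    bandwidth=2000.0,
) -> BasisSet:
    """Simulate a normalized basis set for linear-combination fitting.

    Every entry is the spectrum at unit (1 mM) concentration divided by the
    metabolite's total proton count (per-proton normalization), rendered on a
    common frequency grid.  Bit-identical for a fixed configuration.
    """
    systems = list(systems)
    if not systems:
        raise ValueError("no spin systems given")
    names = [s.name for s in systems]
    if len(set(names)) != len(names):
        raise ValueError("duplicate spin-system names in basis")
    model, fwhm = lineshape
    if fwhm <= 0:
        raise ValueError("lineshape fwhm must be > 0")
    entries, lines, n_protons = {}, {}, {}
    for sys_ in systems:
        freqs, amps = simulate_lines(sys_, seq)
        amps = amps / sys_.n_protons
        lines[sys_.name] = (freqs, amps)
        n_protons[sys_.name] = sys_.n_protons
        entries[sys_.name] = render_lines(
            freqs,
            amps,
            n_points=n_points,
            bandwidth=bandwidth,
            ppm_reference=seq.carrier,
            transmitter_freq=seq.transmitter_freq,
            lineshape=lineshape,
        )
    return BasisSet(
        te=seq.te,
        entries=entries,
        lineshape=tuple(lineshape),
        lines=lines,
        n_protons=n_protons,
        seq=seq,
    )
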