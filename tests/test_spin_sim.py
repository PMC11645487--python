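"""Spin-physics engine: J-modulation, CSDE, rendering and basis export."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ketospec.spin_sim import (
    CapacityError,
    SequenceSpec,
    SpinSystem,
    _Engine,
    build_basis,
    doublet_amplitude,
    render_lines,
    simulate_lines,
    simulate_press_csde,
    simulate_sequence,
    sweep_te,
    target_group_ppm,
)
from ketospec.systems import get_system

PROTOCOL_TES = (40.0, 80.0, 120.0, 144.0, 288.0)


def _two_group(j_hz, shift_a=1.0, shift_x=9.0, n_a=1):
    J = np.array([[0.0, j_hz], [j_hz, 0.0]])
    return SpinSystem("pair", ((shift_a, n_a), (shift_x, 1)), J)


def ratio_vs_te(system, seq, te):
    freqs, amps = simulate_lines(system, replace(seq, te=te))
    n = max(g[1] for g in system.groups)
    return doublet_amplitude(freqs, amps, target_group_ppm(system), seq) / n


class TestJModulation:
    @pytest.mark.parametrize("n_a", [1, 3])
    @pytest.mark.parametrize("kind", ["ideal_se", "slaser"])
    def test_weak_coupling_matches_cosine_closed_form(self, kind, n_a):
        """In the weak-coupling limit the integrated doublet amplitude follows
        cos(pi J TE) to 1e-6 (density-matrix engine vs closed form)."""
        j = 0.002  # Hz; J/(2*delta_nu) ~ 1e-6 at a 1022 Hz separation
        system = _two_group(j, n_a=n_a)
        seq = SequenceSpec(kind=kind, te=100.0)
        for te_s in (0.1, 0.2, 0.35, 0.5):  # seconds
            te = te_s * 1e3
            got = ratio_vs_te(system, seq, te)
            want = np.cos(np.pi * j * te_s)
            assert got == pytest.approx(want, abs=1e-6)

    def test_lactate_fully_inverted_at_te_144(self, slaser_144):
        # second-order (strong-coupling) terms at 3 T leave the inversion at
        # ~-0.998 rather than the weak-coupling -0.9997
        r = ratio_vs_te(get_system("lac"), slaser_144, 144.0)
        assert r <= -0.99

    def test_lactate_antiphase_near_half_inverse_j(self, slaser_144):
        """At TE = 1/(2J) the in-phase doublet nearly vanishes (the residual
        is the second-order strong-coupling contribution)."""
        r = ratio_vs_te(get_system("lac"), slaser_144, 1e3 / (2 * 7.0))
        assert abs(r) < 0.06

    def test_uncoupled_singlet_te_invariant(self, slaser_144):
        amps = [ratio_vs_te(get_system("ace"), slaser_144, te)
                for te in PROTOCOL_TES]
        assert np.allclose(amps, amps[0], rtol=1e-12)
        assert amps[0] == pytest.approx(1.0, rel=1e-9)


class TestSweepTe:
    def test_bhb_maximal_inversion_near_160_ms(self, slaser_144):
        res = sweep_te(get_system("bhb"), slaser_144, np.arange(100.0, 201.0))
        te_best = res[int(np.argmin([r[2] for r in res]))][0]
        assert abs(te_best - 159.0) <= 1.0
        assert round(te_best, -1) == 160.0

    def test_lactate_most_inverted_at_144_among_protocol_tes(self, slaser_144):
        res = sweep_te(get_system("lac"), slaser_144, PROTOCOL_TES)
        te_best = res[int(np.argmin([r[2] for r in res]))][0]
        assert te_best == 144.0

    def test_singlet_amplitude_constant_over_grid(self, slaser_144):
        res = sweep_te(get_system("ace"), slaser_144, PROTOCOL_TES)
        amps = [r[2] for r in res]
        assert np.allclose(amps, amps[0], rtol=1e-12)

    def test_grid_must_be_increasing(self, slaser_144):
        with pytest.raises(ValueError):
            sweep_te(get_system("lac"), slaser_144, [144.0, 100.0])
        with pytest.raises(ValueError):
            sweep_te(get_system("lac"), slaser_144, [])


class TestUnitarity:
    @pytest.mark.parametrize("name", ["lac", "bhb", "glx"])
    def test_density_matrix_hermitian_trace_preserved(self, name, slaser_144):
        """Pulses and delays are unitary: trace and Frobenius norm of the
        density matrix are conserved, hermiticity maintained."""
        from ketospec.spin_sim import _coupled_clusters, _rot_x, _subsystem

        system = get_system(name)
        cluster = max(_coupled_clusters(system), key=len)
        eng = _Engine(_subsystem(system, cluster), slaser_144)
        rho = eng.Iz_tot.copy()
        tr0, norm0 = np.trace(rho), np.linalg.norm(rho)
        R = eng._pulse_op(_rot_x(np.pi / 2), set(range(eng.n_spins)))
        rho = R @ rho @ R.conj().T
        for dt in (0.01, 0.05, 0.072):
            rho = eng._delay(rho, dt)
            assert abs(np.trace(rho) - tr0) < 1e-10
            assert np.linalg.norm(rho) == pytest.approx(norm0, rel=1e-12)
            assert np.linalg.norm(rho - rho.conj().T) < 1e-10


class TestRendering:
    def test_peak_centers_at_configured_shifts(self, slaser_144):
        """Rendered peak maxima sit within one grid step of the preset ppm."""
        for name, ppm in [("ace", 2.22), ("naa", 2.01), ("cho", 3.19)]:
            rec = simulate_sequence(get_system(name), slaser_144,
                                    n_points=8192, lineshape=("lorentzian", 1.0))
            axis = rec.ppm_axis()
            peak_ppm = axis[int(np.argmax(rec.complex_points.real))]
            step = axis[1] - axis[0]
            assert abs(peak_ppm - ppm) <= step

    def test_ppm_axis_monotone_and_referenced(self, slaser_144):
        rec = simulate_sequence(get_system("ace"), slaser_144)
        axis = rec.ppm_axis()
        assert np.all(np.diff(axis) > 0)
        assert axis.min() < 2.22 < axis.max()

    @pytest.mark.parametrize("name,expected_j,center",
                             [("bhb", 6.3, 1.19), ("lac", 7.0, 1.31)])
    def test_doublet_splitting_preserved_by_render(self, name, expected_j,
                                                   center):
        """Peak-picking a finely rendered doublet returns the configured J
        and the configured chemical shift as the doublet midpoint."""
        from ketospec.spin_sim import measure_doublet_splitting

        seq = SequenceSpec(kind="slaser", te=40.0)
        freqs, amps = simulate_lines(get_system(name), seq)
        rec = render_lines(freqs, amps, n_points=65536, bandwidth=2000.0,
                           lineshape=("lorentzian", 0.5))
        assert rec.freq_axis()[1] - rec.freq_axis()[0] <= 0.05
        split, mid = measure_doublet_splitting(
            rec, target_group_ppm(get_system(name)))
        assert split == pytest.approx(expected_j, abs=0.1)
        assert round(mid, 2) == center


class TestPressCsde:
    def test_infinite_bandwidth_recovers_ideal(self):
        seq = SequenceSpec(kind="press", te=144.0, refocus_bandwidth=1e9)
        f_p, a_p = simulate_press_csde(get_system("lac"), seq, return_lines=True)
        f_i, a_i = simulate_lines(get_system("lac"), seq)
        amp_p = doublet_amplitude(f_p, a_p, 1.31, seq)
        amp_i = doublet_amplitude(f_i, a_i, 1.31, seq)
        assert amp_p == pytest.approx(amp_i, rel=1e-6)

    @pytest.mark.parametrize("name", ["lac", "bhb"])
    def test_press_inversion_weaker_than_slaser(self, name, slaser_144):
        press = SequenceSpec(kind="press", te=144.0, refocus_bandwidth=1300.0)
        ppm = target_group_ppm(get_system(name))
        f, a = simulate_press_csde(get_system(name), press, return_lines=True)
        amp_press = doublet_amplitude(f, a, ppm, press)
        f, a = simulate_lines(get_system(name), slaser_144)
        amp_slaser = doublet_amplitude(f, a, ppm, slaser_144)
        assert abs(amp_press) < abs(amp_slaser)
        assert amp_press < 0  # still inverted, just attenuated

    @pytest.mark.parametrize("name", ["lac", "bhb"])
    def test_press_te144_weaker_than_te288(self, name):
        base = SequenceSpec(kind="press", te=144.0, refocus_bandwidth=1300.0)
        ppm = target_group_ppm(get_system(name))
        amps = {}
        for te in (144.0, 288.0):
            f, a = simulate_press_csde(get_system(name), replace(base, te=te),
                                       return_lines=True)
            amps[te] = doublet_amplitude(f, a, ppm, base)
        assert abs(amps[144.0]) < abs(amps[288.0])

    def test_monotone_recovery_with_bandwidth(self):
        base = SequenceSpec(kind="press", te=144.0)
        mags = []
        for bw in (1300.0, 2600.0, 5200.0, 2e4, 1e5):
            f, a = simulate_press_csde(
                get_system("lac"), replace(base, refocus_bandwidth=bw),
                return_lines=True)
            mags.append(abs(doublet_amplitude(f, a, 1.31, base)))
        assert np.all(np.diff(mags) > 0)

    def test_requires_press_kind(self, slaser_144):
        with pytest.raises(ValueError):
            simulate_press_csde(get_system("lac"), slaser_144)


class TestBasis:
    def test_te144_basis_signs(self, kb_basis):
        """Lactate and beta-OHB entries are inverted doublets; the ketone
        singlets stay upright."""
        for name, sign in [("lac", -1), ("bhb", -1), ("acac", +1), ("ace", +1)]:
            freqs, amps = kb_basis.lines[name]
            total = np.sum(amps.real)
            assert np.sign(total) == sign

    def test_basis_normalized_per_proton(self, kb_basis):
        freqs, amps = kb_basis.lines["ace"]
        assert np.sum(amps.real) == pytest.approx(1.0, rel=1e-9)
        assert kb_basis.n_protons["lac"] == 4

    def test_reproducible_bit_identical(self, slaser_144, kb_basis):
        again = build_basis(
            [get_system(n) for n in ("lac", "bhb", "acac", "ace")], slaser_144)
        for name in kb_basis.names:
            assert np.array_equal(again.entries[name].complex_points,
                                  kb_basis.entries[name].complex_points)

    def test_empty_and_duplicate_rejected(self, slaser_144):
        with pytest.raises(ValueError):
            build_basis([], slaser_144)
        with pytest.raises(ValueError):
            build_basis([get_system("lac"), get_system("lac")], slaser_144)
        with pytest.raises(ValueError):
            build_basis([get_system("lac")], slaser_144,
                        lineshape=("lorentzian", 0.0))


class TestValidation:
    def test_spin_system_invariants(self):
        with pytest.raises(ValueError):
            SpinSystem("bad", ((1.0, 1), (2.0, 1)),
                       np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            SpinSystem("bad", ((12.0, 1),))  # shift out of range
        with pytest.raises(ValueError):
            SpinSystem("bad", ((1.0, 0),))  # zero protons

    def test_capacity_error_for_large_coupled_system(self, slaser_144):
        J = np.full((2, 2), 1.0) - np.eye(2)
        big = SpinSystem("big", ((1.0, 6), (2.0, 6)), J * 7.0)
        with pytest.raises(CapacityError):
            simulate_lines(big, slaser_144)

    def test_te_must_be_positive(self):
        with pytest.raises(ValueError):
            SequenceSpec(te=0.0)
        with pytest.raises(ValueError):
            SequenceSpec(te=-5.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(j=st.floats(2.0, 12.0), te=st.floats(20.0, 300.0))
def test_weak_pair_amplitude_bounded_by_proton_count(j, te):
    """|integrated multiplet amplitude| never exceeds the proton count."""
    system = _two_group(j, n_a=3)
    seq = SequenceSpec(kind="ideal_se", te=te)
    freqs, amps = simulate_lines(system, seq)
    amp = doublet_amplitude(freqs, amps, 1.0, seq)
    assert abs(amp) <= 3.0 + 1e-9
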