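import numpy as np
import pytest

from ketospec.spin_sim import SequenceSpec, build_basis
from ketospec.systems import DEFAULT_BASIS_NAMES, get_system


@pytest.fixture(scope="session")
def slaser_144():
    return SequenceSpec(kind="slaser", te=144.0)


@pytest.fixture(scope="session")
def kb_basis(slaser_144):
    """Small basis: the four phantom metabolites at TE 144 ms."""
    systems = [get_system(n) for n in ("lac", "bhb", "acac", "ace")]
    return build_basis(systems, slaser_144)


@pytest.fixture(scope="session")
def full_basis(slaser_144):
    """Default nine-metabolite brain basis at TE 144 ms."""
    systems = [get_system(n) for n in DEFAULT_BASIS_NAMES]
    return build_basis(systems, slaser_144)


@pytest.fixture(scope="session")
def small_scene_kwargs():
    """Compact tumor geometry used by grid-level tests (8x8 for speed)."""
    return dict(grid_dims=(8, 8), radii=(1.2, 2.0, 3.0))


def synth_spectrum(basis, amplitudes, fwhm=5.7, noise_sigma=0.0, rng=None,
                   n_points=1024, bandwidth=2000.0):
    """Render a spectrum as an explicit linear combination of basis entries."""
    from ketospec.spin_sim import SpectrumRecord, render_lines

    spec = np.zeros(n_points, dtype=complex)
    for name, amp in amplitudes.items():
        freqs, amps = basis.lines[name]
        spec += amp * render_lines(
            freqs, amps, n_points=n_points, bandwidth=bandwidth,
            lineshape=("lorentzian", fwhm),
        ).complex_points
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        noise_t = noise_sigma * bandwidth / np.sqrt(n_points) * (
            rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points)
        )
        spec = spec + np.fft.fftshift(np.fft.fft(noise_t)) / bandwidth
    return SpectrumRecord(spec, bandwidth=bandwidth)
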