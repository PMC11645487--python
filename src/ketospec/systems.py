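"""Preset proton spin systems for the brain/ketone-body basis set.

Chemical shifts are in ppm (water at 4.70 ppm), scalar couplings in Hz.
The ketone bodies and lactate carry the quantitatively important multiplets:

* lactate — CH3 doublet at 1.31 ppm, J = 7 Hz to the CH at 4.10 ppm;
* beta-hydroxybutyrate (bhb) — CH3 doublet at 1.19 ppm, J = 6.3 Hz to the
  CH at 4.13 ppm (the CH2 resonances are omitted: they sit under Glx/AcAc
  and carry no quantitative claim here);
* acetoacetate (acac) — two uncoupled singlets at 2.27 and 3.34 ppm
  (the 3.34 ppm peak is also reported at 3.43 ppm; override via
  ``acac_second_peak``);
* acetone (ace) — one six-proton singlet at 2.22 ppm.

The remaining brain metabolites are deliberately simplified spin systems
(dominant resonances only) — adequate for rendering realistic crowded
spectra and for exercising the fitting pipeline, not for strong-coupling
fidelity of, say, full glutamate multiplets.
"""

from __future__ import annotations

import numpy as np

from .spin_sim import SpinSystem

__all__ = ["get_system", "preset_names", "KETONE_BODIES", "DEFAULT_BASIS_NAMES"]


def _sys(name, groups, couplings=None):
    G = len(groups)
    J = np.zeros((G, G))
    if couplings:
        for i, j, val in couplings:
            J[i, j] = J[j, i] = val
    return SpinSystem(name=name, groups=tuple(groups), couplings=J)


def _build_presets(acac_second_peak: float = 3.34):
    return {
        "lac": _sys("lac", [(1.31, 3), (4.10, 1)], [(0, 1, 7.0)]),
        "bhb": _sys("bhb", [(1.19, 3), (4.13, 1)], [(0, 1, 6.3)]),
        "acac": _sys("acac", [(2.27, 3), (acac_second_peak, 3)]),
        "ace": _sys("ace", [(2.22, 6)]),
        # simplified singlet/weakly-coupled models of the standard basis
        "naa": _sys("naa", [(2.01, 3)]),
        "cr": _sys("cr", [(3.03, 3), (3.91, 2)]),
        "cho": _sys("cho", [(3.19, 9)]),
        "mi": _sys("mi", [(3.52, 4), (4.05, 1)], [(0, 1, 4.0)]),
        "glx": _sys(
            "glx", [(3.75, 1), (2.08, 2), (2.35, 2)], [(0, 1, 7.0), (1, 2, 7.0)]
        ),
        "gly": _sys("gly", [(3.55, 2)]),
        "ala": _sys("ala", [(1.47, 3), (3.78, 1)], [(0, 1, 7.2)]),
    }


_PRESETS = _build_presets()

KETONE_BODIES = ("bhb", "acac", "ace")

#: default 1H basis: ketone bodies + the dominant brain metabolites
DEFAULT_BASIS_NAMES = (
    "naa", "cr", "cho", "mi", "glx", "lac", "bhb", "acac", "ace",
)


def preset_names():
    return sorted(_PRESETS)


def get_system(name: str, acac_second_peak: float | None = None) -> SpinSystem:
    """Look up a preset spin system by short name (e.g. ``"lac"``, ``"bhb"``)."""
    key = name.lower()
    if key not in _PRESETS:
        raise KeyError(f"unknown spin system {name!r}; known: {preset_names()}")
    if key == "acac" and acac_second_peak is not None:
        return _build_presets(acac_second_peak)["acac"]
    return _PRESETS[key]
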