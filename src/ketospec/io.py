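"""Persistence: HDF5 containers for basis sets and CSI sessions, NIfTI masks/maps.

HDF5 layout (documented schema, JSON header in attrs):

``basis.h5``
    attrs: ``header`` (JSON: te, lineshape, names, n_protons, axis metadata)
    datasets: ``entries/<name>`` complex spectra, ``lines/<name>/freqs``,
    ``lines/<name>/amps``

``session.h5``
    attrs: ``header`` (JSON: axis metadata, nucleus, session label)
    datasets: ``spectra`` (ny, nx, n_points) complex, ``water_reference``,
    ``b1_map``, ``labels`` (tissue codes)
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .spin_sim import BasisSet, SequenceSpec, SpectrumRecord
from .synthetic_data import CsiSession, SceneTruth, SegMask

__all__ = ["save_basis", "load_basis", "save_session", "load_session",
           "mask_to_nifti", "map_to_nifti"]


def save_basis(basis: BasisSet, path) -> None:
    grid = basis.grid()
    header = dict(
        te=basis.te, lineshape=list(basis.lineshape), names=basis.names,
        n_protons=basis.n_protons, n_points=grid.n_points,
        bandwidth=grid.bandwidth, ppm_reference=grid.ppm_reference,
        transmitter_freq=grid.transmitter_freq, nucleus=grid.nucleus,
        seq=None if basis.seq is None else dict(
            kind=basis.seq.kind, te=basis.seq.te,
            sub_echo_fractions=list(basis.seq.sub_echo_fractions),
            refocus_bandwidth=basis.seq.refocus_bandwidth,
            carrier=basis.seq.carrier,
            transmitter_freq=basis.seq.transmitter_freq,
        ),
    )
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(header)
        for name, rec in basis.entries.items():
            f.create_dataset(f"entries/{name}", data=rec.complex_points)
            freqs, amps = basis.lines[name]
            f.create_dataset(f"lines/{name}/freqs", data=freqs)
            f.create_dataset(f"lines/{name}/amps", data=amps)


def load_basis(path) -> BasisSet:
    with h5py.File(path, "r") as f:
        h = json.loads(f.attrs["header"])
        entries, lines = {}, {}
        for name in h["names"]:
            entries[name] = SpectrumRecord(
                f[f"entries/{name}"][()], bandwidth=h["bandwidth"],
                ppm_reference=h["ppm_reference"], domain="frequency",
                nucleus=h["nucleus"], transmitter_freq=h["transmitter_freq"],
            )
            lines[name] = (f[f"lines/{name}/freqs"][()],
                           f[f"lines/{name}/amps"][()])
    seq = None
    if h.get("seq"):
        s = h["seq"]
        seq = SequenceSpec(
            kind=s["kind"], te=s["te"],
            sub_echo_fractions=tuple(s["sub_echo_fractions"]),
            refocus_bandwidth=s["refocus_bandwidth"], carrier=s["carrier"],
            transmitter_freq=s["transmitter_freq"],
        )
    return BasisSet(te=h["te"], entries=entries,
                    lineshape=tuple(h["lineshape"]), lines=lines,
                    n_protons=h["n_protons"], seq=seq)


def save_session(session: CsiSession, path) -> None:
    header = dict(
        bandwidth=session.bandwidth, ppm_reference=session.ppm_reference,
        transmitter_freq=session.transmitter_freq, domain=session.domain,
        nucleus=session.nucleus, label=session.label,
    )
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(header)
        f.create_dataset("spectra", data=session.spectra)
        if session.water_reference is not None:
            f.create_dataset("water_reference", data=session.water_reference)
        if session.b1_map is not None:
            f.create_dataset("b1_map", data=session.b1_map)
        if session.truth is not None:
            f.create_dataset("labels", data=session.truth.labels)
            f.attrs["voxel_size"] = json.dumps(list(session.truth.voxel_size))


def load_session(path) -> CsiSession:
    with h5py.File(path, "r") as f:
        h = json.loads(f.attrs["header"])
        spectra = f["spectra"][()]
        water = f["water_reference"][()] if "water_reference" in f else None
        b1 = f["b1_map"][()] if "b1_map" in f else None
        truth = None
        if "labels" in f:
            labels = f["labels"][()]
            voxel_size = tuple(json.loads(f.attrs.get("voxel_size", "[6,6,12]")))
            truth = SceneTruth(
                grid_dims=labels.shape, labels=labels, concentrations={},
                compartments={}, voxel_size=voxel_size, session=h["label"],
            )
    return CsiSession(
        spectra=spectra, bandwidth=h["bandwidth"],
        ppm_reference=h["ppm_reference"],
        transmitter_freq=h["transmitter_freq"], domain=h["domain"],
        nucleus=h["nucleus"], water_reference=water, b1_map=b1,
        truth=truth, label=h["label"],
    )


def _affine(voxel_size):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def mask_to_nifti(mask: SegMask, path) -> None:
    data = np.asarray(mask.labels, dtype=np.int16)[..., None]
    nib.save(nib.Nifti1Image(data, _affine(mask.voxel_size)), str(path))


def map_to_nifti(conc_map: np.ndarray, voxel_size, path) -> None:
    data = np.asarray(conc_map, dtype=np.float32)[..., None]
    nib.save(nib.Nifti1Image(data, _affine(voxel_size)), str(path))
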