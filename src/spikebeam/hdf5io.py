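"""Persistence: HDF5 containers for arrays, delimited text for geometry.

Leadfields, source grids, epoched datasets and source maps live in HDF5
groups with shape/unit attributes; sensor arrays round-trip through
delimited text (name, x, y, z[, ox, oy, oz]).
"""

from __future__ import annotations

import h5py
import numpy as np

from .forward import Leadfield, SensorArray, SourceSpace
from .inverse import SourceMap
from .simulate import SpikeDataset

__all__ = [
    "save_leadfield", "load_leadfield",
    "save_source_space", "load_source_space",
    "save_dataset", "load_dataset",
    "save_source_map", "load_source_map",
    "write_sensor_text", "read_sensor_text",
]

_UNITS = {"eeg": "uV/nAm", "meg": "fT/nAm", "meeg": "unit-free"}


def _group(container, name):
    if isinstance(container, (str, bytes)):
        raise TypeError("pass an open h5py.File or Group")
    if name in container:
        del container[name]
    return container.create_group(name)


def save_leadfield(container: h5py.Group, name: str, lf: Leadfield):
    g = _group(container, name)
    g.create_dataset("gain", data=lf.gain)
    g.attrs.update({"modality": lf.modality, "n_sources": lf.n_sources,
                    "k": lf.k, "reference": lf.reference,
                    "units": _UNITS.get(lf.modality, "unknown")})
    if lf.per_source_basis is not None:
        g.create_dataset("per_source_basis", data=lf.per_source_basis)
    g.create_dataset("channel_names",
                     data=np.array(lf.channel_names, dtype="S"))


def load_leadfield(container: h5py.Group, name: str) -> Leadfield:
    g = container[name]
    basis = g["per_source_basis"][()] if "per_source_basis" in g else None
    return Leadfield(
        gain=g["gain"][()], modality=g.attrs["modality"],
        n_sources=int(g.attrs["n_sources"]), k=int(g.attrs["k"]),
        reference=g.attrs["reference"], per_source_basis=basis,
        channel_names=[s.decode() for s in g["channel_names"][()]])


def save_source_space(container: h5py.Group, name: str, src: SourceSpace):
    g = _group(container, name)
    g.create_dataset("points", data=src.points)
    g.create_dataset("indices", data=src.indices)
    g.attrs.update({"spacing_mm": src.spacing, "units": "mm"})


def load_source_space(container: h5py.Group, name: str) -> SourceSpace:
    g = container[name]
    return SourceSpace(points=g["points"][()],
                       spacing=float(g.attrs["spacing_mm"]),
                       indices=g["indices"][()])


def save_dataset(container: h5py.Group, name: str, ds: SpikeDataset):
    g = _group(container, name)
    g.create_dataset("trials", data=ds.trials)
    g.attrs.update({"srate": ds.srate, "peak_index": ds.peak_index,
                    "modality": ds.modality, "tmin": ds.tmin})
    g.create_dataset("channel_names",
                     data=np.array(ds.channel_names, dtype="S"))
    if ds.truth is not None:
        t = g.create_group("truth")
        for key, val in ds.truth.items():
            arr = np.asarray(val)
            if arr.dtype.kind in "ifub":
                t.create_dataset(key, data=arr)


def load_dataset(container: h5py.Group, name: str) -> SpikeDataset:
    g = container[name]
    truth = None
    if "truth" in g:
        truth = {k: (v[()] if v.shape else v[()].item())
                 for k, v in g["truth"].items()}
    return SpikeDataset(
        trials=g["trials"][()], srate=float(g.attrs["srate"]),
        peak_index=int(g.attrs["peak_index"]), modality=g.attrs["modality"],
        channel_names=[s.decode() for s in g["channel_names"][()]],
        tmin=float(g.attrs["tmin"]), truth=truth)


def save_source_map(container: h5py.Group, name: str, sm: SourceMap):
    g = _group(container, name)
    g.create_dataset("values", data=sm.values)
    g.attrs.update({"kind": sm.kind, "method": sm.method,
                    "modality": sm.modality, "model": sm.model,
                    "alpha": sm.alpha})


def load_source_map(container: h5py.Group, name: str) -> SourceMap:
    g = container[name]
    return SourceMap(values=g["values"][()], kind=g.attrs["kind"],
                     method=g.attrs["method"], modality=g.attrs["modality"],
                     model=g.attrs["model"], alpha=float(g.attrs["alpha"]))


def write_sensor_text(path, sensors: SensorArray):
    """Tab-delimited sensor table: name, x, y, z[, ox, oy, oz] (mm)."""
    with open(path, "w") as fh:
        cols = "name\tx\ty\tz"
        if sensors.orientations is not None:
            cols += "\tox\toy\toz"
        fh.write(f"# modality: {sensors.modality}\n{cols}\n")
        for i, name in enumerate(sensors.channel_names):
            row = [name] + [f"{v:.9g}" for v in sensors.positions[i]]
            if sensors.orientations is not None:
                row += [f"{v:.9g}" for v in sensors.orientations[i]]
            fh.write("\t".join(row) + "\n")


def read_sensor_text(path) -> SensorArray:
    with open(path) as fh:
        header = fh.readline()
        modality = header.split(":")[1].strip() if ":" in header else "eeg"
        fh.readline()  # column names
        names, pos, ori = [], [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            names.append(parts[0])
            vals = [float(v) for v in parts[1:]]
            pos.append(vals[:3])
            if len(vals) >= 6:
                ori.append(vals[3:6])
    return SensorArray(positions=np.array(pos),
                       orientations=np.array(ori) if ori else None,
                       modality=modality, channel_names=names)
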