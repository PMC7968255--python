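"""Readers/writers for the pipeline's on-disk artifacts.

Ear waveforms and spectra live in HDF5 containers (datasets created with
``track_times=False`` so identical content produces identical files); trial
tables and tidy results are TSV; axis metadata and reports are JSON;
configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def sha256_arrays(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def save_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _ds(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def save_recordings(path, recordings: dict, sampling_rate: float) -> None:
    """Two-ear session waveforms as per-channel HDF5 datasets."""
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = sampling_rate
        for ear, data in recordings.items():
            _ds(f, ear, np.asarray(data, dtype=np.float32))


def load_recordings(path):
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        recs = {ear: f[ear][()].astype(float) for ear in f.keys()}
    return recs, fs


def save_spectra(path, spectra: dict) -> None:
    """Nested {key: ModulationSpectrum} written as HDF5 groups.

    Keys are '/'-joined strings, e.g. 'S01/left/auditory/induced'.
    """
    with h5py.File(path, "w") as f:
        for key, spec in spectra.items():
            g = f.create_group(key)
            g.attrs["mode"] = spec.mode
            g.attrs["n_trials_used"] = spec.n_trials_used
            g.attrs["df"] = spec.df
            if spec.window is not None:
                g.attrs["window"] = list(spec.window)
            _ds(g, "band_centers", spec.band_centers)
            _ds(g, "mod_freqs", spec.mod_freqs)
            _ds(g, "power", spec.power)
            if spec.evoked_phase is not None:
                _ds(g, "evoked_phase", spec.evoked_phase)


def load_spectra(path) -> dict:
    from .preproc import ModulationSpectrum

    out = {}

    def visit(key, g):
        if isinstance(g, h5py.Group) and "power" in g:
            out[key] = ModulationSpectrum(
                mode=g.attrs["mode"], band_centers=g["band_centers"][()],
                mod_freqs=g["mod_freqs"][()], power=g["power"][()],
                n_trials_used=int(g.attrs["n_trials_used"]),
                df=float(g.attrs["df"]),
                evoked_phase=g["evoked_phase"][()] if "evoked_phase" in g else None,
                window=tuple(g.attrs["window"]) if "window" in g.attrs else None)

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    return out


def save_brain_grid(path, grid) -> None:
    """4-D power array in HDF5 plus a JSON sidecar with the axes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        _ds(f, "power", grid.power)
    sidecar = {
        "freqs_hz": grid.freqs.tolist(),
        "conditions": list(grid.conditions),
        "grid_shape": list(grid.grid_shape),
        "voxel_positions_cm": grid.voxel_positions.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_brain_grid(path):
    from .synth import BrainPowerGrid

    path = Path(path)
    with h5py.File(path, "r") as f:
        power = f["power"][()]
    meta = json.loads(path.with_suffix(".json").read_text())
    return BrainPowerGrid(power=power, freqs=np.asarray(meta["freqs_hz"]),
                          voxel_positions=np.asarray(meta["voxel_positions_cm"]),
                          grid_shape=tuple(meta["grid_shape"]),
                          conditions=tuple(meta["conditions"]))


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())
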