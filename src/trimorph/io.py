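"""File formats: NIfTI volumes, JSON annotations, waveform CSV, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .synth_hemo import FlowWaveformSet
from .synth_valve import VoxelVolume

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_annotation",
    "load_annotation",
    "save_waveforms",
    "load_waveforms",
    "load_yaml",
    "dump_yaml",
]

_WAVEFORM_COLUMNS = ["t_s", "pap_mmHg", "q_pulm_mls", "q_tv_mls"]


def save_nifti(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, RAS+ orientation, mm units."""
    affine = np.diag([vol.spacing, vol.spacing, vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    affine = img.affine
    diag = np.diag(affine)[:3]
    if np.ptp(diag) > 1e-6 or (np.abs(affine[:3, :3] - np.diag(diag)) > 1e-6).any():
        raise InvalidParameterError("only axis-aligned isotropic volumes are supported")
    return VoxelVolume(
        data=np.asarray(img.dataobj, dtype=float),
        spacing=float(diag[0]),
        origin=affine[:3, 3].copy(),
    )


def save_annotation(annotation: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(annotation, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_annotation(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_waveforms(wf: FlowWaveformSet, path: str | Path) -> None:
    """CSV dialect: one header line, columns t_s, pap_mmHg, q_pulm_mls, q_tv_mls."""
    df = pd.DataFrame(
        {
            "t_s": wf.t,
            "pap_mmHg": wf.pap,
            "q_pulm_mls": wf.q_pulm,
            "q_tv_mls": wf.q_tv,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def load_waveforms(
    path: str | Path, heart_rate: float = 60.0, n_cycles: int | None = None
) -> FlowWaveformSet:
    df = pd.read_csv(path)
    missing = set(_WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"waveform CSV missing columns: {sorted(missing)}")
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise InvalidParameterError("waveform record too short")
    # rebuild the nominal uniform time base (CSV rounding would otherwise
    # leave sub-nanosecond jitter)
    fs = round((len(t) - 1) / (t[-1] - t[0]), 6)
    t = np.arange(len(t)) / fs
    if n_cycles is None:
        n_cycles = int(len(t) // (fs * 60.0 / heart_rate))
    return FlowWaveformSet(
        t=t,
        q_pulm=df["q_pulm_mls"].to_numpy(),
        q_tv=df["q_tv_mls"].to_numpy(),
        pap=df["pap_mmHg"].to_numpy(),
        fs=float(round(fs, 9)),
        heart_rate=heart_rate,
        n_cycles=n_cycles,
    )


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
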