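"""On-disk study layout: NIfTI images with JSON sidecars, YAML config, CSV tables.

Image series are stored as NIfTI with axes (x, y, slice[, timepoint]) and a
JSON sidecar carrying the acquisition metadata; label volumes and validity
masks as integer NIfTI; the apex->base slice ordering convention is recorded
in every sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .containers import AcquisitionMeta, ParameterMap, RegionLabels, SliceStack

_AFFINE = np.diag([0.2, 0.2, 1.0, 1.0])  # 200 um in-plane, 1 mm slices


def _img(data: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, _AFFINE)
    img.header.set_data_dtype(data.dtype)
    return img


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _sidecar_path(path) -> str:
    return Path(path).as_posix().replace(".nii", ".json")


def save_stack(path, stack: SliceStack, extra_meta: Optional[dict] = None) -> None:
    """Write a series as NIfTI (x, y, slice, timepoint) + JSON sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(stack.data.transpose(3, 2, 0, 1))  # (x, y, s, t)
    nib.save(_img(data), path)
    sidecar = {"acquisition": stack.meta.to_dict(), "slice_order": "apex_to_base"}
    if extra_meta:
        sidecar.update(extra_meta)
    write_json(_sidecar_path(path), sidecar)


def load_stack(path) -> SliceStack:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not Path(sidecar_path).exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path.name}: {sidecar_path}")
    sidecar = read_json(sidecar_path)
    data = np.asarray(nib.load(path).dataobj)
    stack_data = data.transpose(2, 3, 1, 0)  # back to (s, t, y, x)
    return SliceStack(stack_data, AcquisitionMeta.from_dict(sidecar["acquisition"]))


def save_labels(path, labels: RegionLabels) -> None:
    path = Path(path)
    nib.save(_img(np.ascontiguousarray(labels.labels.transpose(2, 1, 0)).astype(np.int8)), path)
    if labels.edema is not None:
        edema_path = path.as_posix().replace(".nii", "_edema.nii")
        nib.save(_img(np.ascontiguousarray(labels.edema.transpose(2, 1, 0)).astype(np.uint8)),
                 edema_path)


def load_labels(path) -> RegionLabels:
    path = Path(path)
    lab = np.asarray(nib.load(path).dataobj).transpose(2, 1, 0)
    edema_path = Path(path.as_posix().replace(".nii", "_edema.nii"))
    edema = None
    if edema_path.exists():
        edema = np.asarray(nib.load(edema_path).dataobj).transpose(2, 1, 0).astype(bool)
    return RegionLabels(lab.astype(np.int8), edema)


def save_map(path, pmap: ParameterMap, extra_meta: Optional[dict] = None) -> None:
    """Parameter map + validity mask + sidecar with units and scalar diagnostics."""
    path = Path(path)
    nib.save(_img(np.ascontiguousarray(
        np.nan_to_num(pmap.values, nan=0.0).transpose(2, 1, 0)).astype(np.float32)), path)
    nib.save(_img(np.ascontiguousarray(pmap.valid.transpose(2, 1, 0)).astype(np.uint8)),
             path.as_posix().replace(".nii", "_valid.nii"))
    sidecar = {"units": pmap.units, "slice_order": "apex_to_base"}
    for k, v in pmap.diagnostics.items():
        if np.isscalar(v) or isinstance(v, (int, float, str)):
            sidecar[k] = v
    if extra_meta:
        sidecar.update(extra_meta)
    write_json(path.as_posix().replace(".nii", ".json"), sidecar)


def load_map(path) -> ParameterMap:
    path = Path(path)
    values = np.asarray(nib.load(path).dataobj).transpose(2, 1, 0).astype(float)
    valid = np.asarray(nib.load(path.as_posix().replace(".nii", "_valid.nii"))
                       .dataobj).transpose(2, 1, 0).astype(bool)
    sidecar = read_json(path.as_posix().replace(".nii", ".json"))
    values = np.where(valid, values, np.nan)
    diag = {k: v for k, v in sidecar.items() if k not in ("units", "slice_order")}
    return ParameterMap(values, valid, sidecar["units"], diag)


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]
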