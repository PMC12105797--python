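"""Reading and writing voxel fields (NIfTI-1) and flat configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def save_nifti(path, array, spacing=(0.5, 0.5, 2.0)):
    """Write a 3-D field as NIfTI-1 with the grid spacing in the affine."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"failed to write NIfTI volume {path}: {exc}") from exc
    return path


def load_nifti(path):
    """Read a NIfTI volume; returns ``(array, spacing)``."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise OSError(f"failed to read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def export_fields(directory, states, grid, prefix="state"):
    """Write each tumour state's two species as NIfTI volumes.

    Returns the list of written paths; round-tripping through
    :func:`load_nifti` reproduces the arrays bit for bit (float64).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for st in states:
        for species, fieldarr in (("NE", st.N_E), ("NN", st.N_N)):
            p = directory / f"{prefix}_day{int(st.day):03d}_{species}.nii"
            save_nifti(p, fieldarr, grid.spacing)
            paths.append(p)
    return paths


def save_params_yaml(path, variant_id: str, params_dict: dict):
    """Flat key-value dump of one tumour's variant and parameters."""
    payload = {"variant": variant_id, **{k: float(v) for k, v in params_dict.items()}}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_params_yaml(path):
    payload = yaml.safe_load(Path(path).read_text())
    variant = payload.pop("variant")
    return variant, payload


def save_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    return path
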