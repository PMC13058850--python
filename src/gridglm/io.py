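"""NIfTI and JSON serialization of simulated runs, masks and ground truth."""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np

from .bold import BoldRun


def save_bold_nifti(run: BoldRun, path) -> None:
    """Write a run as a 4D NIfTI-1 image (voxels x 1 x 1 x scans), TR in the header."""
    vol = run.data.reshape(run.n_voxels, 1, 1, run.n_scans).astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold_nifti(path, mask_path=None) -> BoldRun:
    """Load a 4D NIfTI as voxels x scans, optionally restricted to a binary mask."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI image")
    n_scans = data.shape[-1]
    flat = data.reshape(-1, n_scans)
    if mask_path is not None:
        flat = flat[load_mask_nifti(mask_path)]
    tr = float(img.header.get_zooms()[3])
    return BoldRun(data=flat, tr=tr)


def save_mask_nifti(mask, path) -> None:
    m = np.asarray(mask, dtype=np.uint8).reshape(-1, 1, 1)
    nib.save(nib.Nifti1Image(m, affine=np.eye(4)), str(path))


def load_mask_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).reshape(-1) > 0.5


def save_ground_truth(run: BoldRun, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(run.ground_truth or {}, fh, indent=1)


def load_ground_truth(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
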