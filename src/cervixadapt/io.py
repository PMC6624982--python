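"""NIfTI import/export of masks and dose grids, with a JSON landmark sidecar.

The grid's LR/AP/SI axis convention maps onto a diagonal RAS-like affine
(spacing on the diagonal, origin in the translation column).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import nibabel as nib
import numpy as np

from .dose import DoseGrid
from .grid import Mask, VoxelGrid

__all__ = ["save_mask", "load_mask", "save_dose", "load_dose",
           "save_landmarks", "load_landmarks"]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = tuple(float(v) for v in np.diag(aff[:3, :3]))
    return VoxelGrid(tuple(int(n) for n in img.shape[:3]), spacing,
                     tuple(float(v) for v in aff[:3, 3]))


def save_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def load_mask(path) -> Mask:
    img = nib.load(str(path))
    return Mask(_grid_from(img), np.asarray(img.dataobj) > 0)


def save_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.data.astype(np.float32), _affine(dose.grid))
    nib.save(img, str(path))


def load_dose(path) -> DoseGrid:
    img = nib.load(str(path))
    return DoseGrid(_grid_from(img), np.asarray(img.dataobj, dtype=np.float32))


def save_landmarks(landmarks: Dict[str, np.ndarray], path, **metadata) -> None:
    payload = {"landmarks_mm": {k: [float(x) for x in v] for k, v in landmarks.items()},
               "metadata": metadata}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_landmarks(path) -> Dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in payload["landmarks_mm"].items()}
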