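"""On-disk formats for cohorts: PNG stills/masks, text PET grids, CSV tables.

A cohort directory contains::

    cohort.csv            per-node table (identity, truth, latent features)
    panel.csv             rater-panel scores (node_id, rater, read, score)
    manifest.csv          node_id -> relative image/mask/PET paths
    images/<id>.png       8-bit RGB elastogram stills
    masks/<id>.png        8-bit single-channel ROI masks (0/255)
    pet/<id>.txt          whitespace text voxel grid (activity MBq/g)
    pet/<id>.mask.txt     0/1 text delineation grid
    pet/<id>.json         sidecar: dims, voxel_mm, dose_mbq, weight_g

PET grids are stored as plain text (no DICOM): one flattened grid per file
with the shape recorded in the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .pet import AcquisitionInfo, PetVoi

__all__ = [
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_pet_voi",
    "load_pet_voi",
]


def save_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.asarray(image, dtype=np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def load_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def save_pet_voi(
    stem: str | Path, voi: PetVoi, acq: AcquisitionInfo
) -> tuple[Path, Path, Path]:
    """Write <stem>.txt, <stem>.mask.txt and <stem>.json; returns the paths."""
    stem = Path(stem)
    grid_path = stem.with_suffix(".txt")
    mask_path = stem.with_suffix(".mask.txt")
    sidecar_path = stem.with_suffix(".json")
    np.savetxt(grid_path, voi.activity.reshape(voi.activity.shape[0], -1), fmt="%.9e")
    np.savetxt(mask_path, voi.mask.reshape(voi.mask.shape[0], -1), fmt="%d")
    sidecar = {
        "dims": list(voi.activity.shape),
        "voxel_mm": list(voi.voxel_mm),
        "dose_mbq": acq.injected_dose_mbq,
        "weight_g": acq.body_weight_g,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return grid_path, mask_path, sidecar_path


def load_pet_voi(stem: str | Path) -> tuple[PetVoi, AcquisitionInfo]:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    dims = tuple(sidecar["dims"])
    activity = np.loadtxt(stem.with_suffix(".txt")).reshape(dims)
    mask = np.loadtxt(stem.with_suffix(".mask.txt")).reshape(dims).astype(bool)
    voi = PetVoi(activity=activity, voxel_mm=tuple(sidecar["voxel_mm"]), mask=mask)
    acq = AcquisitionInfo(
        injected_dose_mbq=sidecar["dose_mbq"], body_weight_g=sidecar["weight_g"]
    )
    return voi, acq


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
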