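"""Readers and writers: NIfTI volumes/planar images, ROI JSON, cohort CSV,
YAML configs and provenance-stamped result JSON.

Units are fixed at the I/O boundary — mm for spacing, cm^3 for Svol, ng/L for
PTH, mg/dL for calcium/phosphorus, ug/L for 25(OH)D — and validated on read;
no unit inference is attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import ActivityVolume, PlanarImage
from .planar import Roi

__all__ = [
    "save_volume", "load_volume", "save_planar", "load_planar",
    "roi_to_json", "roi_from_json", "save_cohort", "load_cohort",
    "load_yaml_config", "write_result_json", "voi_to_label_volume",
]

COHORT_COLUMNS = {
    "id": "patient identifier",
    "age": "years",
    "sex": "M/F",
    "pth": "parathormone, ng/L",
    "calcium": "serum calcium, mg/dL",
    "phosphorus": "serum phosphorus, mg/dL",
    "vitd": "25(OH) vitamin D, ug/L",
    "elbr": "early lesion/background ratio",
    "dlbr": "delayed lesion/background ratio",
    "eltr": "early lesion/thyroid ratio",
    "dltr": "delayed lesion/thyroid ratio",
    "svol": "scintigraphic adenoma volume, cm^3",
    "pth_svol": "PTH / Svol, ng/L per cm^3",
    "ri": "retention index (eLTR - dLTR)/eLTR",
    "severity": "mild | marked hypercalcemia",
    "location": "adenoma site label (metadata)",
}


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: ActivityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.counts.astype(np.float32), _affine(volume.voxel_spacing))
    img.header.set_zooms(volume.voxel_spacing)
    img.header["descrip"] = f"time_point={volume.time_point}".encode()
    nib.save(img, str(path))


def load_volume(path: str | Path, time_point: str | None = None) -> ActivityVolume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing in header")
    if time_point is None:
        desc = bytes(img.header["descrip"]).decode(errors="ignore")
        time_point = "delayed" if "delayed" in desc else "early"
    return ActivityVolume(
        counts=np.asarray(img.dataobj, dtype=float),
        voxel_spacing=zooms,
        time_point=time_point,
    )


def save_planar(image: PlanarImage, path: str | Path) -> None:
    sp = image.pixel_spacing
    img = nib.Nifti1Image(image.counts.astype(np.float32)[:, :, None], _affine((sp, sp, 1.0)))
    img.header.set_zooms((sp, sp, 1.0))
    img.header["descrip"] = f"time_point={image.time_point}".encode()
    nib.save(img, str(path))


def load_planar(path: str | Path, time_point: str | None = None) -> PlanarImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"{path}: expected a 2-D planar image")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()
    if not np.isclose(zooms[0], zooms[1]):
        raise ValueError(f"{path}: planar pixels must be square")
    if time_point is None:
        desc = bytes(img.header["descrip"]).decode(errors="ignore")
        time_point = "delayed" if "delayed" in desc else "early"
    return PlanarImage(counts=data, pixel_spacing=float(zooms[0]), time_point=time_point)


def roi_to_json(roi: Roi, path: str | Path, image_ref: str | None = None) -> None:
    payload = {
        "label": roi.label,
        "source": roi.source,
        "pixels": roi.pixels.tolist(),
        "image": image_ref,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def roi_from_json(path: str | Path) -> Roi:
    payload = json.loads(Path(path).read_text())
    return Roi(
        pixels=np.asarray(payload["pixels"], dtype=int),
        label=payload.get("label", "lesion"),
        source=payload.get("source", "manual"),
    )


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" in df.columns and df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient ids")
    for col in ("pth", "calcium", "phosphorus", "vitd", "svol"):
        if col in df.columns and (df[col].dropna() <= 0).any():
            raise ValueError(f"{path}: column {col!r} must be positive")
    return df


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_result_json(result: dict, path: str | Path, seed: int | None = None,
                      config: dict | None = None) -> None:
    """Write a result bundle with a provenance block (seed, config hash,
    package version)."""
    payload = {
        "provenance": {
            "package": "parascint",
            "version": __version__,
            "seed": seed,
            "config_sha256_16": _config_hash(config or {}),
        },
        "result": _jsonable(result),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def voi_to_label_volume(voi, shape, spacing) -> ActivityVolume:
    """Render a VOI as a binary label volume (for NIfTI export)."""
    lab = np.zeros(shape, dtype=float)
    lab[voi.voxels[:, 0], voi.voxels[:, 1], voi.voxels[:, 2]] = 1.0
    return ActivityVolume(lab, spacing, time_point="early")
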