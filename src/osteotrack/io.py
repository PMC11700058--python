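"""Volume, transform and table serialization.

Volumes travel as multi-page TIFF stacks (slice = z) with a JSON sidecar
carrying voxel size, calibration tag and free metadata; spectra and curves
as two-column CSV (see their classes); transforms as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .volcore import DensityVolume, RigidTransform

__all__ = ["save_volume", "load_volume", "save_transform", "load_transform"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(volume: DensityVolume, path, sidecar=None) -> Path:
    """Write a volume as multi-page TIFF + JSON sidecar; returns sidecar path."""
    path = Path(path)
    tifffile.imwrite(path, volume.values.astype(np.float32))
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    meta = {
        "voxel_size_um": volume.voxel_size_um,
        "calibration": volume.calibration,
        "meta": _jsonable(volume.meta),
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)
    return sidecar


def load_volume(path, sidecar=None) -> DensityVolume:
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    with open(sidecar) as fh:
        meta = json.load(fh)
    return DensityVolume(
        values.astype(np.float64),
        float(meta["voxel_size_um"]),
        meta.get("calibration", "raw"),
        meta.get("meta", {}),
    )


def save_transform(transform: RigidTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)


def load_transform(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
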