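"""File interfaces: NIfTI volumes, YAML configs, CSV/JSON metrics.

Images and maps are written as NIfTI-1 with the voxel size in the affine;
configurations round-trip losslessly through YAML; per-subject metrics go
to tidy CSV (one row per subject/arm) and run manifests to JSON with
content checksums for reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "save_nifti",
    "load_nifti",
    "config_to_yaml",
    "config_from_yaml",
    "file_checksum",
    "write_manifest",
]


def save_nifti(volume: np.ndarray, voxel_mm, path) -> None:
    """Write a 3-D (or 4-D, frames last) volume with voxel size in mm."""
    affine = np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(tuple(voxel_mm) + ((1.0,) if volume.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.header.get_zooms()[:3]


def _plain(obj):
    """Recursively convert dataclasses/arrays/tuples to YAML-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_yaml(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=True)


def config_from_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config_hash: str, stage_seconds: dict, files: list, path=None) -> dict:
    out_dir = Path(out_dir)
    manifest = {
        "config_sha256": config_hash,
        "stage_seconds": {k: round(float(v), 3) for k, v in stage_seconds.items()},
        "files": {
            str(Path(f).relative_to(out_dir)): file_checksum(f) for f in files
        },
    }
    target = Path(path) if path else out_dir / "manifest.json"
    with open(target, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
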