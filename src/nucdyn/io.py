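"""Reading and writing volumes, label grids, and tabular artifacts.

Volumes travel as multi-page TIFF with axis order (t, z, y, x) plus a YAML
sidecar carrying the calibration (voxel size, frame interval) and the full
array shape; the sidecar is required on read — resolution is never
guessed.  Tables are CSV with units in the column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import LabelVolume, VolumeSeries

__all__ = ["write_volume", "read_volume", "write_labels", "read_labels",
           "sidecar_path"]

_AXES = "TZYX"


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".yaml")


def _write_sidecar(path: Path, shape, voxel_size, frame_interval) -> None:
    meta = {
        "axes": _AXES,
        "shape": [int(s) for s in shape],
        "voxel_size_um": [float(v) for v in voxel_size],
        "frame_interval_s": float(frame_interval),
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta))


def _read_sidecar(path: Path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing calibration sidecar {sc}; volumes require a YAML sidecar "
            "with axes/shape/voxel_size_um/frame_interval_s — resolution is never guessed"
        )
    meta = yaml.safe_load(sc.read_text())
    missing = {"axes", "shape", "voxel_size_um", "frame_interval_s"} - set(meta)
    if missing:
        raise ValueError(f"sidecar {sc} missing fields: {sorted(missing)}")
    if meta["axes"] != _AXES:
        raise ValueError(
            f"unsupported axis order {meta['axes']!r} in {sc}: expected {_AXES!r} "
            "(add a leading T axis of length 1 for single-frame volumes)"
        )
    return meta


def write_volume(path: str | Path, vol: VolumeSeries) -> Path:
    """Write intensities as multi-page TIFF plus the calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    _write_sidecar(path, vol.data.shape, vol.voxel_size, vol.frame_interval)
    return path


def read_volume(path: str | Path) -> VolumeSeries:
    """Read a TIFF volume; lossless for integer data."""
    path = Path(path)
    meta = _read_sidecar(path)
    data = tifffile.imread(path).reshape(meta["shape"])
    return VolumeSeries(data, tuple(meta["voxel_size_um"]), meta["frame_interval_s"])


def write_labels(path: str | Path, labels: LabelVolume) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")
    _write_sidecar(path, labels.labels.shape, labels.voxel_size, labels.frame_interval)
    return path


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    meta = _read_sidecar(path)
    data = tifffile.imread(path).reshape(meta["shape"]).astype(np.int32)
    return LabelVolume(data, tuple(meta["voxel_size_um"]), meta["frame_interval_s"])
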