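"""Shared containers for volumetric time-lapse data.

Conventions used throughout the package:

* axis order is ``(t, z, y, x)`` for every 4D array;
* z index 0 is the apical-most slice, depth increases basally;
* physical positions are reported at voxel centers, i.e. the center of
  voxel index ``i`` along an axis with pitch ``d`` sits at ``(i + 0.5) * d``
  micrometers;
* times are seconds internally; speeds are reported in um/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeSeries", "LabelVolume", "voxel_centers"]


def voxel_centers(n: int, pitch: float) -> np.ndarray:
    """Physical coordinates (um) of the voxel centers along one axis."""
    return (np.arange(n) + 0.5) * pitch


@dataclass
class VolumeSeries:
    """A 4D fluorescence intensity grid with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(t, z, y, x)``; non-negative finite intensities.
    voxel_size:
        ``(dz, dy, dx)`` in micrometers.
    frame_interval:
        Time between consecutive frames, seconds.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (t,z,y,x) data, got ndim={self.data.ndim}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_size}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.voxel_size
        return np.isclose(dz, dx) and np.isclose(dy, dx)


@dataclass
class LabelVolume:
    """Integer label grid aligned to a :class:`VolumeSeries`.

    0 is background; positive labels are nuclei.  ``track_ids`` maps each
    label to its track identity once frames have been linked (identity map
    before linking).
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float
    track_ids: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise ValueError(f"expected 4D (t,z,y,x) labels, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.labels[t]

    def labels_in_frame(self, t: int) -> np.ndarray:
        vals = np.unique(self.labels[t])
        return vals[vals > 0]
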