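"""Apical-basal nuclear positioning from cross-sectional area profiles.

Columnar-epithelium nuclei are often top-heavy (more volume apical than
basal), so the widest z-plane is a poor positional readout.  Instead the
nuclear *midplane* is defined as the midpoint between the two half-maximum
crossings of the per-plane cross-sectional-area profile; nuclei whose
profile is cut by the imaging volume above half-max are untrackable and
excluded.  Depths feed three positional categories: the apical exclusion
zone (top 2 um), the apical 10 um (roughly the apical third of a 30-35 um
cell), and everything basal to that.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import LabelVolume

__all__ = [
    "AreaProfile",
    "DepthCategory",
    "area_profile",
    "nuclear_midplane",
    "depth_category",
    "category_fractions",
    "apical_surface_z",
    "midplane_table",
    "EXCLUSION_ZONE_UM",
    "APICAL_ZONE_UM",
]

EXCLUSION_ZONE_UM = 2.0
APICAL_ZONE_UM = 10.0


@dataclass
class AreaProfile:
    """Cross-sectional area of one nucleus versus depth, one frame.

    ``z_um`` are plane depths (um, strictly increasing, apical to basal);
    ``area_um2`` the label's area in each plane.  ``valid`` is False when
    the label was absent from the frame.
    """

    z_um: np.ndarray
    area_um2: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, float)
        self.area_um2 = np.asarray(self.area_um2, float)
        if self.z_um.size > 1 and not np.all(np.diff(self.z_um) > 0):
            raise ValueError("z positions must be strictly increasing")
        if np.any(self.area_um2 < 0):
            raise ValueError("areas must be non-negative")


class DepthCategory(Enum):
    EXCLUSION_ZONE = "exclusion_zone"  # <= 2 um; implies apical10
    APICAL10 = "apical10"  # <= 10 um
    BASAL = "basal"  # > 10 um


def area_profile(labels: LabelVolume | np.ndarray, track_id: int, frame: int = 0,
                 voxel_size: tuple[float, float, float] | None = None) -> AreaProfile:
    """Per-z-plane area (um^2) of one label, ordered apical to basal."""
    if isinstance(labels, LabelVolume):
        grid = labels.frame(frame)
        dz, dy, dx = labels.voxel_size
    else:
        grid = np.asarray(labels)
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
        dz, dy, dx = voxel_size
    counts = (grid == track_id).sum(axis=(1, 2))
    z = (np.arange(grid.shape[0]) + 0.5) * dz
    if counts.sum() == 0:
        return AreaProfile(z, np.zeros_like(z, float), valid=False)
    return AreaProfile(z, counts * dy * dx, valid=True)


def nuclear_midplane(profile: AreaProfile, apical_reference: float = 0.0) -> float:
    """Midpoint between the two half-max flanks of an area profile.

    Finds the maximal area ``A*``, locates the outermost apical-side and
    basal-side crossings of ``A*/2`` by linear interpolation between
    adjacent planes, and returns the midpoint of the two crossing depths,
    expressed relative to ``apical_reference``.  Returns NaN (untrackable)
    when the profile is empty or touches either end of the volume at or
    above half-max, because the flank there cannot be located.
    """
    a = profile.area_um2
    z = profile.z_um
    if not profile.valid or a.size == 0 or a.max() <= 0:
        return float("nan")
    a_star = a.max()
    half = a_star / 2.0
    if a[0] >= half or a[-1] >= half:
        return float("nan")
    above = np.flatnonzero(a >= half)
    i_lo, i_hi = above[0], above[-1]
    # outermost crossings: interpolate on the rising and falling segments
    zl = np.interp(half, [a[i_lo - 1], a[i_lo]], [z[i_lo - 1], z[i_lo]])
    zr = np.interp(half, [a[i_hi + 1], a[i_hi]], [z[i_hi + 1], z[i_hi]])
    return float((zl + zr) / 2.0 - apical_reference)


def apical_surface_z(labels_frame: np.ndarray, dz: float) -> float:
    """Tissue-wide apical reference: top edge of the apical-most foreground slice."""
    fg = np.flatnonzero((labels_frame > 0).any(axis=(1, 2)))
    if fg.size == 0:
        return float("nan")
    return float(fg[0] * dz)


def depth_category(depth: float) -> set[DepthCategory]:
    """Positional category (or categories) of one midplane depth.

    Depths within the apical 2 um belong to both the exclusion zone and
    the apical-10-um population.
    """
    if not np.isfinite(depth) or depth < 0:
        raise ValueError(f"depth must be a finite non-negative number, got {depth}")
    cats = set()
    if depth <= EXCLUSION_ZONE_UM:
        cats.add(DepthCategory.EXCLUSION_ZONE)
    if depth <= APICAL_ZONE_UM:
        cats.add(DepthCategory.APICAL10)
    else:
        cats.add(DepthCategory.BASAL)
    return cats


def category_fractions(depths: np.ndarray | list[float]) -> dict[str, float]:
    """Population fractions per positional category at one time point.

    Each fraction divides the category count by the total valid population;
    exclusion-zone nuclei also count toward apical10, so
    ``apical10 + basal == 1`` and ``exclusion_zone <= apical10``.  Raises
    when no valid depth is supplied.
    """
    d = np.asarray(depths, float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no valid nuclei at this time point")
    n = d.size
    return {
        "exclusion_zone": float((d <= EXCLUSION_ZONE_UM).sum() / n),
        "apical10": float((d <= APICAL_ZONE_UM).sum() / n),
        "basal": float((d > APICAL_ZONE_UM).sum() / n),
        "n": int(n),
    }


def midplane_table(labels: LabelVolume, apical_reference: float | None = 0.0) -> pd.DataFrame:
    """Midplane depth and category per (track, frame).

    ``apical_reference`` fixes the apical surface depth; pass ``None`` to
    estimate it tissue-wide per frame from the apical-most foreground
    slice.  Categories are left empty for untrackable (NaN) midplanes.
    """
    rows = []
    for t in range(labels.n_frames):
        frame = labels.frame(t)
        ref = apical_surface_z(frame, labels.voxel_size[0]) if apical_reference is None \
            else apical_reference
        ids = np.unique(frame)
        ids = ids[ids > 0]
        for lab in ids:
            prof = area_profile(labels, int(lab), t)
            depth = nuclear_midplane(prof, apical_reference=ref)
            valid = bool(np.isfinite(depth)) and depth >= 0
            cats = sorted(c.value for c in depth_category(depth)) if valid else []
            rows.append(
                {
                    "track_id": int(lab),
                    "frame": t,
                    "t_s": t * labels.frame_interval,
                    "midplane_depth_um": depth,
                    "valid": valid,
                    "category": "+".join(cats),
                }
            )
    return pd.DataFrame(rows)
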