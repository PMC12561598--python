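"""Scanner geometry, breast contour stacks and the geometric primitives.

A microwave breast-imaging scanner holds the pendulous breast immersed in a
coupling liquid inside a cylindrical container; a circular probe array slides
vertically and acquires one coronal slice per height ``h``.  The breast
surface reconstructed from each slice is a simple closed polygon in the slice
plane, with the scanner axis at the origin.  Depth is measured downward from
the bed level, ``z = h_bed - h``, so the slice closest to the chest wall has
the smallest ``z``.

Everything downstream (the proximity filter, the area-profile filter, volume
integration and the cohort statistics) consumes the types defined here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "ScannerGeometry",
    "ContourSlice",
    "ContourStack",
    "DistanceProfile",
    "AreaProfile",
    "height_to_z",
    "slice_area",
    "distance_to_array",
    "distance_profile",
    "area_profile",
    "stack_volume",
]

logger = logging.getLogger(__name__)

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class ScannerGeometry:
    """Fixed geometry of the cylindrical scanner.

    Parameters
    ----------
    array_radius : float
        Internal radius of the probe-array circle, mm.
    h_bed : float
        Height of the examination bed / table level, mm.
    h_uppermost : float
        Uppermost probe-array scan position, mm.  Must lie below the bed,
        i.e. ``h_uppermost < h_bed``.
    height_step : float
        Vertical spacing between consecutive scan positions, mm.
    """

    array_radius: float = 90.0
    h_bed: float = 182.5
    h_uppermost: float = 158.0
    height_step: float = 5.0

    def __post_init__(self) -> None:
        if self.array_radius <= 0:
            raise ValueError("array_radius must be positive")
        if self.height_step <= 0:
            raise ValueError("height_step must be positive")
        if not self.h_uppermost < self.h_bed:
            raise ValueError("h_uppermost must lie below h_bed")

    @property
    def z_min(self) -> float:
        """Shallowest reachable depth, mm (24.5 under defaults)."""
        return self.h_bed - self.h_uppermost


def height_to_z(h: float, geometry: ScannerGeometry) -> float:
    """Map a probe-array height to scanner depth, ``z = h_bed - h``.

    Raises
    ------
    ValueError
        If ``h`` exceeds the bed level (no probe position exists there).
    """
    if h > geometry.h_bed:
        raise ValueError(
            f"invalid probe position h={h} mm above bed level {geometry.h_bed} mm"
        )
    return geometry.h_bed - h


def _dedup_consecutive(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(points[1:] != points[:-1], axis=1)
    # closing vertex identical to the first is also dropped
    if keep.sum() > 1 and np.all(points[keep][-1] == points[keep][0]):
        idx = np.flatnonzero(keep)
        keep[idx[-1]] = False
    if not keep.all():
        logger.warning("dropped %d duplicate consecutive vertices", (~keep).sum())
    return points[keep]


@dataclass(frozen=True)
class ContourSlice:
    """One coronal breast-surface contour: a simple closed polygon at height ``h``."""

    h: float
    points: np.ndarray  # (n, 2) float array of (x, y) vertices, mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of planar coordinates")
        pts = _dedup_consecutive(pts)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValueError(f"contour at h={self.h} has fewer than 3 distinct vertices")
        poly = Polygon(pts)
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError(f"contour at h={self.h} is not a simple polygon")

    def polygon(self) -> Polygon:
        return Polygon(self.points)


def slice_area(slc: ContourSlice) -> float:
    """Enclosed area of one contour, mm², by the shoelace formula.

    Positive regardless of vertex orientation or starting vertex.
    """
    pts = slc.points
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def distance_to_array(
    slc: ContourSlice, geometry: ScannerGeometry
) -> tuple[float, float, float]:
    """Min / mean / max radial skin-to-array distance over the vertices, mm.

    Each vertex sits at radius ``hypot(x, y)`` from the scanner axis; its
    distance to the probe-array circle is ``array_radius - hypot(x, y)``.

    Raises
    ------
    ValueError
        If any vertex lies on or outside the array circle.
    """
    r = np.hypot(slc.points[:, 0], slc.points[:, 1])
    d = geometry.array_radius - r
    if np.any(d <= 0):
        raise ValueError(
            f"contour at h={slc.h} has vertices on/outside the array circle "
            f"(max radius {r.max():.2f} >= {geometry.array_radius} mm)"
        )
    return float(d.min()), float(d.mean()), float(d.max())


@dataclass(frozen=True)
class ContourStack:
    """Per-height contour stack, sorted by increasing depth z."""

    geometry: ScannerGeometry
    slices: tuple[ContourSlice, ...]

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        object.__setattr__(self, "slices", slices)
        if not slices:
            raise ValueError("empty contour stack")
        z = self.z
        if np.any(np.diff(z) <= 0):
            dup = z[np.flatnonzero(np.diff(z) <= 0)[0] + 1]
            raise ValueError(f"slice depths not strictly increasing near z={dup} mm")
        if z[0] < self.geometry.z_min - 1e-9:
            raise ValueError(
                f"first slice z={z[0]} mm above reachable z_min={self.geometry.z_min} mm"
            )

    @property
    def z(self) -> np.ndarray:
        g = self.geometry
        return np.array([height_to_z(s.h, g) for s in self.slices])

    @property
    def z_top(self) -> float:
        """Depth of the shallowest (nearest-chest) scanned slice, mm."""
        return float(self.z[0])

    @property
    def z_bottom(self) -> float:
        return float(self.z[-1])

    @property
    def extent(self) -> float:
        """Total scanned vertical extent, mm."""
        return self.z_bottom - self.z_top

    def __len__(self) -> int:
        return len(self.slices)


@dataclass(frozen=True)
class DistanceProfile:
    """Per-slice skin-to-array distance summary (Fig-9-style curves)."""

    z: np.ndarray
    d_min: np.ndarray
    d_mean: np.ndarray
    d_max: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z", "d_min", "d_mean", "d_max"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.z) == len(self.d_min) == len(self.d_mean) == len(self.d_max)):
            raise ValueError("profile arrays must have equal length")

    def __len__(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class AreaProfile:
    """Per-slice contour area, mm², against depth z (the *areas* vector)."""

    z: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "area", np.asarray(self.area, dtype=float))
        if len(self.z) != len(self.area):
            raise ValueError("z and area must have equal length")
        if np.any(self.area <= 0):
            raise ValueError("contour areas must be positive")

    def __len__(self) -> int:
        return len(self.z)


def distance_profile(stack: ContourStack) -> DistanceProfile:
    stats = [distance_to_array(s, stack.geometry) for s in stack.slices]
    dmin, dmean, dmax = (np.array(v) for v in zip(*stats))
    return DistanceProfile(z=stack.z, d_min=dmin, d_mean=dmean, d_max=dmax)


def area_profile(stack: ContourStack) -> AreaProfile:
    return AreaProfile(z=stack.z, area=np.array([slice_area(s) for s in stack.slices]))


def stack_volume(
    stack: ContourStack, z_from: float | None = None, z_to: float | None = None
) -> float:
    """Breast volume between two depths, mL, by trapezoidal area integration.

    The area profile is integrated over slices with ``z_from <= z <= z_to``;
    half-slices beyond the first and last sample inside the range are not
    extrapolated.  Restricting the range never increases the result.

    Raises
    ------
    ValueError
        If ``z_from > z_to`` or a nonempty range contains no slices.
    """
    prof = area_profile(stack)
    z_from = stack.z_top if z_from is None else float(z_from)
    z_to = stack.z_bottom if z_to is None else float(z_to)
    if z_from > z_to:
        raise ValueError(f"z_from={z_from} exceeds z_to={z_to}")
    if z_from == z_to:
        return 0.0
    mask = (prof.z >= z_from - 1e-9) & (prof.z <= z_to + 1e-9)
    if not mask.any():
        raise ValueError(f"no slices inside requested range [{z_from}, {z_to}] mm")
    return float(np.trapezoid(prof.area[mask], prof.z[mask])) / MM3_PER_ML
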