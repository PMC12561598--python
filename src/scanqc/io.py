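"""Reading and writing contour stacks, profiles and surface meshes.

Two on-disk dialects carry a contour stack:

* JSON — ``{"geometry": {"array_radius_mm", "h_bed_mm", "h_uppermost_mm",
  "height_step_mm"}, "slices": [{"h_mm": ..., "points": [[x, y], ...]}, ...]}``
* flat CSV — columns ``slice_id,h_mm,x_mm,y_mm`` with vertex order preserved
  within each slice (geometry travels separately or uses defaults).

Profiles export as CSV; the stacked surface can be written as a Wavefront OBJ
loft for inspection in any mesh viewer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    AreaProfile,
    ContourSlice,
    ContourStack,
    DistanceProfile,
    ScannerGeometry,
)

__all__ = [
    "read_stack",
    "write_stack",
    "read_stack_csv",
    "write_stack_csv",
    "write_distance_profile",
    "write_area_profile",
    "write_obj",
]


def _build_stack(geometry: ScannerGeometry, raw_slices: list[tuple[float, np.ndarray]]) -> ContourStack:
    slices = []
    seen_h: set[float] = set()
    for i, (h, pts) in enumerate(raw_slices):
        if h in seen_h:
            raise ValueError(f"duplicate height h={h} mm (slice {i})")
        seen_h.add(h)
        try:
            slices.append(ContourSlice(h=h, points=pts))
        except ValueError as e:
            raise ValueError(f"slice {i} (h={h} mm): {e}") from e
    slices.sort(key=lambda s: -s.h)  # increasing z = decreasing h
    return ContourStack(geometry=geometry, slices=tuple(slices))


def read_stack(path: str | Path) -> ContourStack:
    """Load a contour stack from the JSON dialect, validating all invariants."""
    with open(path) as f:
        doc = json.load(f)
    g = doc.get("geometry", {})
    geometry = ScannerGeometry(
        array_radius=g.get("array_radius_mm", 90.0),
        h_bed=g.get("h_bed_mm", 182.5),
        h_uppermost=g.get("h_uppermost_mm", 158.0),
        height_step=g.get("height_step_mm", 5.0),
    )
    raw = [
        (float(s["h_mm"]), np.asarray(s["points"], dtype=float))
        for s in doc["slices"]
    ]
    return _build_stack(geometry, raw)


def write_stack(stack: ContourStack, path: str | Path) -> None:
    g = stack.geometry
    doc = {
        "geometry": {
            "array_radius_mm": g.array_radius,
            "h_bed_mm": g.h_bed,
            "h_uppermost_mm": g.h_uppermost,
            "height_step_mm": g.height_step,
        },
        "slices": [
            {"h_mm": s.h, "points": s.points.tolist()} for s in stack.slices
        ],
    }
    with open(path, "w") as f:
        json.dump(doc, f)


def read_stack_csv(
    path: str | Path, geometry: ScannerGeometry | None = None
) -> ContourStack:
    """Load the flat CSV dialect (``slice_id,h_mm,x_mm,y_mm``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    geometry = geometry or ScannerGeometry()
    raw = []
    for _sid, grp in df.groupby("slice_id", sort=True):
        h = float(grp["h_mm"].iloc[0])
        raw.append((h, grp[["x_mm", "y_mm"]].to_numpy(dtype=float)))
    return _build_stack(geometry, raw)


def write_stack_csv(stack: ContourStack, path: str | Path) -> None:
    rows = []
    for sid, s in enumerate(stack.slices):
        for x, y in s.points:
            rows.append((sid, s.h, x, y))
    pd.DataFrame(rows, columns=["slice_id", "h_mm", "x_mm", "y_mm"]).to_csv(
        path, index=False
    )


def write_distance_profile(profile: DistanceProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "z_mm": profile.z,
            "d_min": profile.d_min,
            "d_mean": profile.d_mean,
            "d_max": profile.d_max,
        }
    ).to_csv(path, index=False)


def write_area_profile(profile: AreaProfile, path: str | Path) -> None:
    pd.DataFrame({"z_mm": profile.z, "area_mm2": profile.area}).to_csv(
        path, index=False
    )


def write_obj(stack: ContourStack, path: str | Path) -> None:
    """Write the lofted breast surface as a triangulated Wavefront OBJ.

    Consecutive contours are resampled to a common vertex count and stitched
    with triangle strips; z points downward as in scanner coordinates.
    """
    n = max(len(s.points) for s in stack.slices)
    rings = []
    for s, z in zip(stack.slices, stack.z):
        pts = s.points
        # resample by arc-length-uniform interpolation over the closed loop
        closed = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        ti = np.linspace(0.0, t[-1], n, endpoint=False)
        x = np.interp(ti, t, closed[:, 0])
        y = np.interp(ti, t, closed[:, 1])
        rings.append(np.column_stack([x, y, np.full(n, z)]))
    lines = []
    for ring in rings:
        for v in ring:
            lines.append(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}")
    for k in range(len(rings) - 1):
        a, b = k * n, (k + 1) * n
        for i in range(n):
            j = (i + 1) % n
            lines.append(f"f {a+i+1} {b+i+1} {a+j+1}")
            lines.append(f"f {b+i+1} {b+j+1} {a+j+1}")
    Path(path).write_text("\n".join(lines) + "\n")
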