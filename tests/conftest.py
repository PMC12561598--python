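"""Shared builders for analytic contour stacks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from scanqc import ContourSlice, ContourStack, ScannerGeometry


def circle_points(
    radius: float, n: int = 180, center: tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
) -> np.ndarray:
    theta = np.linspace(0.0, 2 * math.pi, n, endpoint=False) + phase
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def circular_stack(
    radii_by_z: dict[float, float],
    geometry: ScannerGeometry | None = None,
    n: int = 180,
) -> ContourStack:
    """Stack of centred circular contours with prescribed radius per depth."""
    g = geometry or ScannerGeometry()
    slices = [
        ContourSlice(h=g.h_bed - z, points=circle_points(r, n=n))
        for z, r in sorted(radii_by_z.items())
    ]
    return ContourStack(geometry=g, slices=tuple(slices))


def polygon_area_factor(n: int) -> float:
    """Regular n-gon area relative to its circumscribed circle."""
    return 0.5 * n * math.sin(2 * math.pi / n) / math.pi


@pytest.fixture
def geometry() -> ScannerGeometry:
    return ScannerGeometry()
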