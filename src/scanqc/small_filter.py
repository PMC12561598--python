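"""Area-profile filter for small pendulous breasts.

Small breasts immerse deeper into the scanner and frequently drag
non-mammary structures (excess chest tissue, bone, pectoral muscle) into the
imaging scene, artificially widening the reconstructed surface near the
chest wall.  This tool analyses the per-height contour area profile and
rejects the distorted near-chest prefix using two indicators:

* *area-steep-decrease* — an abrupt relative area drop between adjacent
  heights inside a near-chest search window;
* *area-breakpoint* — an almost-flat topmost segment of a piecewise-linear
  approximation of the area profile, followed by a consistently decreasing
  segment; the cut is placed at their boundary.

The breakpoint indicator is consulted when steep-decrease filtering is
absent or too shallow to be useful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import FilterDecision
from .geometry import AreaProfile, ContourStack, area_profile

__all__ = [
    "AreaTrendThresholds",
    "PiecewiseFit",
    "Segment",
    "piecewise_fit",
    "steep_decrease_detect",
    "breakpoint_detect",
    "apply_small_tool",
]


@dataclass(frozen=True)
class AreaTrendThresholds:
    """Configuration of the small-breasts area-profile filter.

    r_steep : relative adjacent-slice area drop that counts as steep.
    top_window : mm — depth window below the scan top searched for steep drops.
    s_flat_frac_per_mm : a fitted segment is "flat" when |slope| is at most
        this fraction of the profile maximum area, per mm of depth.
    s_dec_frac_per_mm : (negative) a segment is a "consistent decrease" when
        its slope is at or below this fraction of the maximum area per mm.
    l_dec_min : mm — minimum extent of the decreasing segment.
    min_useful_delta : mm — steep-decrease rejections shallower than this are
        deemed insufficient and the breakpoint indicator is consulted.
    max_segments : cap on the piecewise-fit segment count.
    """

    r_steep: float = 0.20
    top_window: float = 25.0
    s_flat_frac_per_mm: float = 0.01
    s_dec_frac_per_mm: float = -0.02
    l_dec_min: float = 10.0
    min_useful_delta: float = 5.0
    max_segments: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.r_steep < 1:
            raise ValueError("r_steep must be in (0, 1)")
        if self.s_flat_frac_per_mm <= 0:
            raise ValueError("s_flat_frac_per_mm must be positive")
        if self.s_dec_frac_per_mm >= 0:
            raise ValueError("s_dec_frac_per_mm must be negative")
        if self.max_segments < 2:
            raise ValueError("max_segments must be at least 2")


@dataclass(frozen=True)
class Segment:
    """One fitted line over a contiguous run of profile samples."""

    i_start: int
    i_end: int  # inclusive sample indices
    z_start: float
    z_end: float
    slope: float  # mm² per mm
    intercept: float  # mm², area at z = 0 extrapolation

    @property
    def extent(self) -> float:
        return self.z_end - self.z_start


@dataclass(frozen=True)
class PiecewiseFit:
    """Piecewise-linear least-squares approximation of an area profile."""

    segments: tuple[Segment, ...]
    sse: float

    def __len__(self) -> int:
        return len(self.segments)


def _segment_costs(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of the least-squares line over samples i..j (j > i)."""
    n = len(z)
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = z[i : j + 1], a[i : j + 1]
            slope, intercept = np.polyfit(x, y, 1)
            r = y - (slope * x + intercept)
            cost[i, j] = float(r @ r)
    return cost


def piecewise_fit(
    areas: AreaProfile, max_segments: int = 5, n_segments: int | None = None
) -> PiecewiseFit:
    """Optimal segmented linear fit with breakpoints on sample boundaries.

    For each candidate segment count ``k`` the exact optimum is found by
    dynamic programming over all breakpoint placements (every segment spans
    at least two samples); ``k`` is then chosen by a BIC-style penalized
    score, ``n·ln(SSE/n) + 2k·ln(n)``.  Passing ``n_segments`` skips model
    selection and returns the exact optimum for that segment count.

    Raises
    ------
    ValueError
        If the profile has fewer than 4 samples, or fewer than
        ``2 · n_segments`` samples when a segment count is forced.
    """
    z, a = areas.z, areas.area
    n = len(z)
    if n < 4:
        raise ValueError("piecewise fit needs at least 4 samples")
    if n_segments is not None and n < 2 * n_segments:
        raise ValueError(f"insufficient profile: {n} samples for {n_segments} segments")
    kmax = n_segments if n_segments is not None else min(max_segments, n // 2)
    cost = _segment_costs(z, a)

    # D[k][j] = best SSE covering samples 0..j with k segments; P tracks cuts
    D = np.full((kmax + 1, n), np.inf)
    P = np.full((kmax + 1, n), -1, dtype=int)
    D[1] = cost[0]
    for k in range(2, kmax + 1):
        for j in range(2 * k - 1, n):
            # last segment starts at m+1 and spans >= 2 samples
            best, arg = np.inf, -1
            for m in range(2 * (k - 1) - 1, j - 1):
                v = D[k - 1][m] + cost[m + 1, j]
                if v < best:
                    best, arg = v, m
            D[k][j], P[k][j] = best, arg

    if n_segments is not None:
        k_best = n_segments
    else:
        logn = np.log(n)
        floor = max(1e-12, 1e-16 * float(a.max()) ** 2)
        scores = [
            n * np.log(max(D[k][n - 1], floor) / n) + 2 * k * logn
            for k in range(1, kmax + 1)
        ]
        k_best = int(np.argmin(scores)) + 1

    # backtrack segment boundaries
    bounds = []
    j, k = n - 1, k_best
    while k >= 1:
        i = 0 if k == 1 else P[k][j] + 1
        bounds.append((i, j))
        j, k = i - 1, k - 1
    bounds.reverse()

    segments = []
    for i, j in bounds:
        slope, intercept = np.polyfit(z[i : j + 1], a[i : j + 1], 1)
        segments.append(
            Segment(
                i_start=i, i_end=j, z_start=float(z[i]), z_end=float(z[j]),
                slope=float(slope), intercept=float(intercept),
            )
        )
    return PiecewiseFit(segments=tuple(segments), sse=float(D[k_best][n - 1]))


def steep_decrease_detect(
    areas: AreaProfile, thresholds: AreaTrendThresholds = AreaTrendThresholds()
) -> FilterDecision:
    """Flag an abrupt relative area drop between adjacent near-chest slices.

    Scanning downward within ``top_window`` of the scan top, adjacent pairs
    with a relative drop exceeding ``r_steep`` are collected; the cut is the
    lower depth of the deepest pair in the topmost contiguous run of steep
    pairs.  Steep pairs below a gap are ignored.
    """
    z, a = areas.z, areas.area
    z_top = float(z[0])
    drops = (a[:-1] - a[1:]) / a[:-1]
    in_window = z[1:] <= z_top + thresholds.top_window
    steep = np.flatnonzero((drops > thresholds.r_steep) & in_window)
    if steep.size == 0:
        return FilterDecision(
            tool="small", triggered=False, criterion="none",
            z_cut=z_top, delta_height=0.0,
        )
    run_end = steep[0]
    for idx in steep[1:]:
        if idx == run_end + 1:
            run_end = idx
        else:
            break
    z_cut = float(z[run_end + 1])
    return FilterDecision(
        tool="small", triggered=True, criterion="area-steep-decrease",
        z_cut=z_cut, delta_height=z_cut - z_top,
        flagged_z=frozenset(z[steep[0] : run_end + 2].tolist()),
    )


def breakpoint_detect(
    areas: AreaProfile,
    fit: PiecewiseFit,
    thresholds: AreaTrendThresholds = AreaTrendThresholds(),
) -> FilterDecision:
    """Flag a flat-then-decreasing breakpoint in the fitted area profile.

    Triggers when the topmost fitted segment is flat (|slope| within
    ``s_flat_frac_per_mm`` of the maximum area) and the next segment
    decreases at or below ``s_dec_frac_per_mm`` of the maximum area per mm
    over at least ``l_dec_min`` mm.  The cut is placed at the flat segment's
    last sample.
    """
    z_top = float(areas.z[0])
    none = FilterDecision(
        tool="small", triggered=False, criterion="none",
        z_cut=z_top, delta_height=0.0,
    )
    if len(fit) < 2:
        return none
    a_max = float(areas.area.max())
    top, nxt = fit.segments[0], fit.segments[1]
    flat = abs(top.slope) <= thresholds.s_flat_frac_per_mm * a_max
    decreasing = (
        nxt.slope <= thresholds.s_dec_frac_per_mm * a_max
        and nxt.extent >= thresholds.l_dec_min
    )
    if not (flat and decreasing):
        return none
    z_cut = top.z_end
    return FilterDecision(
        tool="small", triggered=True, criterion="area-breakpoint",
        z_cut=z_cut, delta_height=z_cut - z_top,
        flagged_z=frozenset(areas.z[: top.i_end + 1].tolist()),
    )


def apply_small_tool(
    stack: ContourStack, thresholds: AreaTrendThresholds = AreaTrendThresholds()
) -> FilterDecision:
    """Run the area-profile filter on a contour stack.

    The steep-decrease indicator is evaluated first; when its rejected
    extent falls short of ``min_useful_delta`` the breakpoint indicator is
    consulted and, if it triggers, wins.
    """
    if len(stack) < 4:
        raise ValueError("area-profile filtering needs at least 4 slices")
    areas = area_profile(stack)
    steep = steep_decrease_detect(areas, thresholds)
    if steep.delta_height < thresholds.min_useful_delta:
        fit = piecewise_fit(areas, thresholds.max_segments)
        bp = breakpoint_detect(areas, fit, thresholds)
        if bp.triggered:
            return bp
    return steep
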