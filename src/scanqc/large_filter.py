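"""Proximity filter for large pendulous breasts.

Large breasts deform under the buoyancy of the coupling liquid and bring the
near-chest skin close to the probe array, where antenna cross-coupling and
strong surface reflections degrade image fidelity.  This tool flags the
coronal slices whose minimum skin-to-array distance falls under a threshold
and rejects the contiguous run of flagged slices at the top (near-bed end) of
the scan.

Two thresholds are used: a *primary* one, and a laxer *soft* one that takes
over when primary filtering would reject an excessive fraction of the scan —
keeping the retained partial scan clinically useful for very large breasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decision import FilterDecision
from .geometry import ContourStack, DistanceProfile, distance_profile

__all__ = ["ProximityThresholds", "flag_proximity", "cut_from_top", "apply_large_tool"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProximityThresholds:
    """Configuration of the large-breasts proximity filter.

    t_primary : mm — primary minimum-distance threshold (slices with
        ``d_min < t_primary`` are flagged).
    t_soft : mm — laxer fallback threshold, ``t_soft <= t_primary``.
    max_primary_fraction : fraction of the total scanned extent above which
        primary filtering counts as excessive and the soft threshold is used.
    """

    t_primary: float = 10.0
    t_soft: float = 5.0
    max_primary_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.t_soft <= self.t_primary:
            raise ValueError("require 0 < t_soft <= t_primary")
        if not 0 < self.max_primary_fraction <= 1:
            raise ValueError("max_primary_fraction must be in (0, 1]")


def flag_proximity(profile: DistanceProfile, threshold: float) -> frozenset:
    """Depths of slices whose minimum skin-to-array distance is under ``threshold``.

    Comparison is strict: a slice exactly at the threshold is not flagged.
    """
    if len(profile) == 0:
        raise ValueError("empty distance profile")
    return frozenset(profile.z[profile.d_min < threshold].tolist())


def cut_from_top(flagged_z: frozenset, stack: ContourStack) -> float:
    """Bottom depth of the contiguous flagged run starting at the topmost slice.

    Returns the topmost scanned depth itself when the top slice is unflagged.
    Flagged slices not connected to the top are ignored (the rejected region
    must be a contiguous near-chest prefix) and logged.
    """
    z = stack.z
    z_cut = float(z[0])
    connected = True
    stray = False
    for zi in z:
        if zi in flagged_z:
            if connected:
                z_cut = float(zi)
            else:
                stray = True
        else:
            connected = False
    if stray:
        logger.warning("ignoring flagged slices not contiguous with the scan top")
    return z_cut


def _decide(stack: ContourStack, profile: DistanceProfile, threshold: float,
            criterion: str) -> FilterDecision:
    flagged = flag_proximity(profile, threshold)
    if float(stack.z[0]) not in flagged:
        return FilterDecision(
            tool="large", triggered=False, criterion="none",
            z_cut=stack.z_top, delta_height=0.0, flagged_z=flagged,
        )
    z_cut = cut_from_top(flagged, stack)
    return FilterDecision(
        tool="large", triggered=True, criterion=criterion,
        z_cut=z_cut, delta_height=z_cut - stack.z_top, flagged_z=flagged,
    )


def apply_large_tool(
    stack: ContourStack, thresholds: ProximityThresholds = ProximityThresholds()
) -> FilterDecision:
    """Run the proximity filter on a contour stack.

    The primary threshold is evaluated first; if the extent it would reject
    exceeds ``max_primary_fraction`` of the total scanned extent, the decision
    is re-evaluated with the soft threshold and reported with
    ``criterion="soft"``.
    """
    if len(stack) < 2:
        raise ValueError("proximity filtering needs at least 2 slices")
    profile = distance_profile(stack)
    primary = _decide(stack, profile, thresholds.t_primary, "primary")
    if not primary.triggered:
        return primary
    if primary.delta_height > thresholds.max_primary_fraction * stack.extent:
        logger.info(
            "primary criterion rejects %.1f of %.1f mm: excessive, using soft",
            primary.delta_height, stack.extent,
        )
        return _decide(stack, profile, thresholds.t_soft, "soft")
    return primary
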