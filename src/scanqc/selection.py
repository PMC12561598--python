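"""Combining filter decisions into the final partial-scan definition.

The deeper of the two tools' cuts wins.  When a lesion known from reference
imaging (mammography, ultrasound or MRI) lies inside the region a cut would
discard, the full scan is retained instead — a per-breast, binary override —
so that known disease is never excluded from image formation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decision import FilterDecision
from .geometry import ContourStack, stack_volume

__all__ = [
    "LesionAnnotation",
    "ScanSelection",
    "select_scan",
    "categorize_volume",
    "volume_concordance",
]


@dataclass(frozen=True)
class LesionAnnotation:
    """Known lesion position from a reference modality.

    z_center : depth (mm, scanner coordinates) of the lesion centre.
    label : free-text note, e.g. histology or reference modality.
    """

    z_center: float
    label: str = ""


def categorize_volume(v: float) -> str:
    """Breast size category: small (<600 mL), medium (600-1200 mL), large (>1200 mL).

    Both category boundaries belong to the medium group.
    """
    if v <= 0:
        raise ValueError("volume must be positive")
    if v < 600.0:
        return "small"
    if v <= 1200.0:
        return "medium"
    return "large"


def volume_concordance(
    mwbi: float, reference: float, band: float = 200.0
) -> tuple[float, bool]:
    """Scan-vs-reference volume discrepancy (mL) and whether it is within band."""
    if mwbi <= 0 or reference <= 0:
        raise ValueError("volumes must be positive")
    disc = mwbi - reference
    return disc, abs(disc) <= band


@dataclass(frozen=True)
class ScanSelection:
    """Final partial-scan definition for one breast."""

    breast_id: str
    large_decision: FilterDecision
    small_decision: FilterDecision
    z_cut_final: float
    override_full_scan: bool
    full_volume: float
    selected_volume: float
    size_category: str
    reference_volume: float | None = None
    volume_discrepancy: float | None = None

    @property
    def any_triggered(self) -> bool:
        return self.large_decision.triggered or self.small_decision.triggered

    @property
    def partial_selected(self) -> bool:
        """A strict partial scan was the selected output."""
        return self.any_triggered and not self.override_full_scan


def select_scan(
    stack: ContourStack,
    large: FilterDecision,
    small: FilterDecision,
    lesion: LesionAnnotation | None = None,
    breast_id: str = "",
    reference_volume: float | None = None,
) -> ScanSelection:
    """Combine both tools' cuts, apply the lesion override, compute volumes.

    ``z_cut_final`` is the deeper of the two cuts.  A lesion with
    ``z_center < z_cut_final`` would fall in the rejected region, so the
    full scan is retained (override).  Volumes come from trapezoidal
    integration of the contour areas over the full and selected depth ranges.

    Raises
    ------
    ValueError
        If the lesion annotation lies outside the scanned depth range.
    """
    if lesion is not None and not (stack.z_top <= lesion.z_center <= stack.z_bottom):
        raise ValueError(
            f"lesion at z={lesion.z_center} mm outside scanned range "
            f"[{stack.z_top}, {stack.z_bottom}] mm"
        )
    z_cut = max(large.z_cut, small.z_cut)
    override = lesion is not None and lesion.z_center < z_cut
    full = stack_volume(stack)
    selected = full if override else stack_volume(stack, z_from=z_cut)
    disc = None
    if reference_volume is not None:
        disc, _ = volume_concordance(full, reference_volume)
    basis = reference_volume if reference_volume is not None else full
    return ScanSelection(
        breast_id=breast_id,
        large_decision=large,
        small_decision=small,
        z_cut_final=z_cut,
        override_full_scan=override,
        full_volume=full,
        selected_volume=selected,
        size_category=categorize_volume(basis),
        reference_volume=reference_volume,
        volume_discrepancy=disc,
    )
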