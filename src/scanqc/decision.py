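"""Outcome record shared by the two partial-scan filters."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FilterDecision:
    """One filter tool's verdict on a contour stack.

    Attributes
    ----------
    tool : str
        ``"large"`` (proximity filter) or ``"small"`` (area-profile filter).
    triggered : bool
        Whether any slice was rejected.
    criterion : str
        Which indicator fired: ``primary`` / ``soft`` for the proximity tool,
        ``area-steep-decrease`` / ``area-breakpoint`` for the area tool,
        ``none`` otherwise.
    z_cut : float
        Depth (mm) of the bottom of the rejected near-chest region; equals the
        topmost scanned depth when nothing is rejected.
    delta_height : float
        Rejected vertical extent, mm: ``z_cut`` minus the topmost scanned depth.
    flagged_z : frozenset[float]
        Depths of the individual slices the indicator flagged.
    """

    tool: str
    triggered: bool
    criterion: str
    z_cut: float
    delta_height: float
    flagged_z: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.tool not in ("large", "small"):
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.criterion not in (
            "primary",
            "soft",
            "area-steep-decrease",
            "area-breakpoint",
            "none",
        ):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.delta_height < 0:
            raise ValueError("delta_height must be non-negative")
        if self.triggered != (self.delta_height > 0):
            raise ValueError("triggered must hold exactly when delta_height > 0")
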