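"""YAML configuration for the two filter tools' thresholds."""

from __future__ import annotations

from pathlib import Path

import yaml

from .large_filter import ProximityThresholds
from .small_filter import AreaTrendThresholds

__all__ = ["load_config", "default_config"]

_LARGE_KEYS = {
    "t_primary_mm": "t_primary",
    "t_soft_mm": "t_soft",
    "max_primary_fraction": "max_primary_fraction",
}
_SMALL_KEYS = {
    "r_steep": "r_steep",
    "top_window_mm": "top_window",
    "s_flat_frac_per_mm": "s_flat_frac_per_mm",
    "s_dec_frac_per_mm": "s_dec_frac_per_mm",
    "l_dec_min_mm": "l_dec_min",
    "min_useful_delta_mm": "min_useful_delta",
    "max_segments": "max_segments",
}


def default_config() -> tuple[ProximityThresholds, AreaTrendThresholds]:
    return ProximityThresholds(), AreaTrendThresholds()


def load_config(path: str | Path) -> tuple[ProximityThresholds, AreaTrendThresholds]:
    """Read threshold overrides from a YAML file.

    Recognised keys: ``large_tool.{t_primary_mm, t_soft_mm,
    max_primary_fraction}`` and ``small_tool.{r_steep, top_window_mm,
    s_flat_frac_per_mm, s_dec_frac_per_mm, l_dec_min_mm,
    min_useful_delta_mm, max_segments}``.  Unknown keys raise.
    """
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    large_doc = doc.get("large_tool", {}) or {}
    small_doc = doc.get("small_tool", {}) or {}
    for section, known in (("large_tool", _LARGE_KEYS), ("small_tool", _SMALL_KEYS)):
        unknown = set((doc.get(section) or {})) - set(known)
        if unknown:
            raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")
    large = ProximityThresholds(**{_LARGE_KEYS[k]: v for k, v in large_doc.items()})
    small = AreaTrendThresholds(**{_SMALL_KEYS[k]: v for k, v in small_doc.items()})
    return large, small
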