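"""Cohort-level statistics: Wilson score and Student-t confidence intervals.

Proportions (which breasts a tool affected, which criterion applied, how
often the lesion override retained the full scan) are summarised with the
Wilson score interval, which stays inside [0, 1] and behaves well at the
small counts typical of a pilot study.  Mean rejected extents are summarised
with Student-t intervals under approximate normality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .selection import ScanSelection

__all__ = ["ProportionCI", "MeanCI", "wilson_ci", "t_ci", "cohort_summary", "CohortSummary"]


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    point: float
    lo: float
    hi: float
    conf: float = 0.95


@dataclass(frozen=True)
class MeanCI:
    mean: float
    sd: float
    n: int
    lo: float
    hi: float
    conf: float = 0.95


def wilson_ci(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion (no continuity correction).

    With ``p = k/n`` and z the two-sided normal quantile, the interval is
    centred at ``(p + z²/2n) / (1 + z²/n)`` with half-width
    ``z·sqrt(p(1-p)/n + z²/4n²) / (1 + z²/n)``.

    Raises
    ------
    ValueError
        If ``n < 1`` or ``k`` outside ``[0, n]``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = sps.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return ProportionCI(k=k, n=n, point=p, lo=lo, hi=hi, conf=conf)


def t_ci(mean: float, sd: float, n: int, conf: float = 0.95) -> MeanCI:
    """Student-t confidence interval for a mean from summary statistics.

    Raises
    ------
    ValueError
        If ``n < 2`` or ``sd < 0``.
    """
    if n < 2:
        raise ValueError("t interval needs n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = sps.t.ppf(0.5 + conf / 2.0, n - 1) * sd / math.sqrt(n)
    return MeanCI(mean=mean, sd=sd, n=n, lo=mean - half, hi=mean + half, conf=conf)


@dataclass(frozen=True)
class CohortSummary:
    """Tables summarising a set of scan selections.

    groups : one row per tool / criterion / overall group with trigger counts,
        Wilson CI of the proportion and the t-CI of the rejected extent.
    category_crosstab : size-category × tool-outcome counts.
    """

    groups: pd.DataFrame
    category_crosstab: pd.DataFrame


def _group_row(name: str, k: int, n: int, deltas: Sequence[float], conf: float) -> dict:
    ci = wilson_ci(k, n, conf)
    row = {
        "group": name, "k": k, "n": n,
        "prop": ci.point, "prop_lo": ci.lo, "prop_hi": ci.hi,
        "mean_delta_mm": np.nan, "sd_mm": np.nan,
        "mean_lo": np.nan, "mean_hi": np.nan,
    }
    d = np.asarray(deltas, dtype=float)
    if d.size == 1:
        # mean is reported; a one-sample t interval is undefined
        row["mean_delta_mm"] = float(d[0])
    elif d.size >= 2:
        m, s = float(d.mean()), float(d.std(ddof=1))
        ci_m = t_ci(m, s, d.size, conf)
        row.update(mean_delta_mm=m, sd_mm=s, mean_lo=ci_m.lo, mean_hi=ci_m.hi)
    return row


def cohort_summary(
    selections: Sequence[ScanSelection], conf: float = 0.95
) -> CohortSummary:
    """Summarise trigger rates, rejected extents and overrides over a cohort.

    Rows of ``groups``: each tool (proportion of the whole cohort affected,
    mean rejected extent among affected breasts), each criterion within its
    tool (proportion of the tool's triggered cases), partial-scan selection
    over the whole cohort, and the lesion override among triggered cases.

    Raises
    ------
    ValueError
        On an empty cohort.
    """
    if not selections:
        raise ValueError("empty cohort")
    n = len(selections)
    rows: list[dict] = []

    for tool in ("large", "small"):
        decs = [getattr(s, f"{tool}_decision") for s in selections]
        trig = [d for d in decs if d.triggered]
        rows.append(
            _group_row(f"{tool}_tool", len(trig), n, [d.delta_height for d in trig], conf)
        )
        criteria = sorted({d.criterion for d in trig})
        for crit in criteria:
            sub = [d for d in trig if d.criterion == crit]
            rows.append(
                _group_row(
                    f"{tool}_tool:{crit}", len(sub), max(len(trig), 1),
                    [d.delta_height for d in sub], conf,
                )
            )

    partial = [s for s in selections if s.partial_selected]
    rows.append(_group_row("partial_scan_selected", len(partial), n, [], conf))
    triggered = [s for s in selections if s.any_triggered]
    overridden = [s for s in triggered if s.override_full_scan]
    rows.append(
        _group_row("override_among_triggered", len(overridden), max(len(triggered), 1), [], conf)
    )

    groups = pd.DataFrame(rows)

    outcome = [
        "override" if s.override_full_scan
        else ("partial" if s.partial_selected else "full")
        for s in selections
    ]
    crosstab = pd.crosstab(
        pd.Series([s.size_category for s in selections], name="size_category"),
        pd.Series(outcome, name="outcome"),
    )
    return CohortSummary(groups=groups, category_crosstab=crosstab)
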