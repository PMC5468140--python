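"""Pellet-group counting rules, development-phase assignment, raw summaries.

A pellet group is a cluster of at least 20 pellets; when pellets are spread
evenly over a plot they are counted individually and binned using the mean
group size of 127 pellets (20-146 pellets = one group, 147-273 = two, ...).
Survey years map onto wind-farm development phases (preconstruction,
construction, operation); one clearing year is excluded from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GROUP_MIN_PELLETS",
    "PELLETS_PER_GROUP",
    "PHASES",
    "PhaseMap",
    "DEFAULT_PHASE_MAP",
    "pellets_to_groups",
    "presence_indicator",
    "phase_of_year",
    "phase_mean_difference",
    "percent_reduction",
    "round_half_away",
    "validate_records",
]

GROUP_MIN_PELLETS = 20  # minimum cluster size that counts as a group
PELLETS_PER_GROUP = 127  # mean pellets per group, used for binning large scatters

PHASES = ("excluded", "preconstruction", "construction", "operation")


@dataclass(frozen=True)
class PhaseMap:
    """Mapping from survey year to development phase."""

    mapping: dict = field(
        default_factory=lambda: {
            2009: "excluded",
            2010: "preconstruction",
            2011: "construction",
            2012: "construction",
            2013: "operation",
            2014: "operation",
            2015: "operation",
        }
    )

    def __post_init__(self):
        bad = set(self.mapping.values()) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases in map: {sorted(bad)}")

    @property
    def analysis_years(self) -> list[int]:
        return sorted(y for y, p in self.mapping.items() if p != "excluded")

    @property
    def years(self) -> list[int]:
        return sorted(self.mapping)


DEFAULT_PHASE_MAP = PhaseMap()


def pellets_to_groups(n_pellets: int) -> int:
    """Bin a raw pellet count into pellet groups.

    Fewer than 20 pellets is no group; from 20 on, each further 127 pellets
    (the mean group size) opens a new group, reproducing the bins
    [20, 146] -> 1 and [147, 273] -> 2.
    """
    n = int(n_pellets)
    if n < 0:
        raise ValueError("pellet count must be >= 0")
    if n < GROUP_MIN_PELLETS:
        return 0
    return 1 + (n - GROUP_MIN_PELLETS) // PELLETS_PER_GROUP


def presence_indicator(groups: int) -> int:
    """1 iff at least one pellet group was recorded."""
    g = int(groups)
    if g < 0:
        raise ValueError("group count must be >= 0")
    return int(g >= 1)


def phase_of_year(year: int, phase_map: PhaseMap = DEFAULT_PHASE_MAP) -> str:
    """Development phase represented by the survey in ``year``."""
    try:
        return phase_map.mapping[int(year)]
    except KeyError:
        raise KeyError(f"year {year} has no phase assignment") from None


def phase_mean_difference(
    records: pd.DataFrame,
    phase_map: PhaseMap,
    phase_a: str,
    phase_b: str,
) -> tuple[float, float]:
    """Mean pellet groups per plot in phase A minus phase B, with its SE.

    Plot-year observations are pooled within each phase; the standard error
    is the independent two-sample formula sqrt(s_a^2/n_a + s_b^2/n_b) on the
    plot-level counts (sample variances, ddof=1).
    """
    if "groups" not in records.columns or "year" not in records.columns:
        raise ValueError("records need 'year' and 'groups' columns")
    phases = records["year"].map(lambda y: phase_of_year(y, phase_map))
    out = []
    for ph in (phase_a, phase_b):
        vals = records.loc[phases == ph, "groups"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"phase {ph!r} has {len(vals)} observations; need >= 2")
        out.append(vals)
    a, b = out
    diff = a.mean() - b.mean()
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    return float(diff), float(se)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_reduction(mean_pre: float, mean_post: float) -> int:
    """Percent reduction in mean pellet groups per plot, nearest integer."""
    if mean_pre <= 0:
        raise ValueError("percent reduction undefined for mean_pre <= 0")
    return int(round_half_away(100.0 * (1.0 - mean_post / mean_pre)))


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check survey records against the counting rules.

    Returns a DataFrame of violations (possibly empty) with columns
    ``row``, ``rule`` and ``detail``.  Rules: nonnegative counts, presence
    consistent with groups, and (when raw pellets are recorded) groups
    consistent with the binning rule.
    """
    problems = []

    def add(i, rule, detail):
        problems.append({"row": i, "rule": rule, "detail": detail})

    for i, rec in records.iterrows():
        groups = rec.get("groups")
        pellets = rec.get("pellets")
        if pd.isna(groups):
            add(i, "missing-groups", "groups is required")
            continue
        if groups < 0:
            add(i, "negative-groups", f"groups={groups}")
        if pellets is not None and not pd.isna(pellets):
            if pellets < 0:
                add(i, "negative-pellets", f"pellets={pellets}")
            elif pellets_to_groups(int(pellets)) != int(groups):
                add(i, "binning", f"pellets={int(pellets)} implies "
                    f"groups={pellets_to_groups(int(pellets))}, recorded {int(groups)}")
        if "presence" in records.columns and not pd.isna(rec["presence"]):
            if int(rec["presence"]) != presence_indicator(int(groups)):
                add(i, "presence", f"presence={rec['presence']} but groups={groups}")
    return pd.DataFrame(problems, columns=["row", "rule", "detail"])
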