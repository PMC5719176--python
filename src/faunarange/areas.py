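"""Per-species area accounting and fauna-wide aggregate statistics.

The per-species table carries the three period areas (km^2) and the
proportion of range lost over the three intervals.  The aggregate
summary pools areas across species: total proportion of combined
original (Holocene) range lost, its split into losses before and after
AD 1900 (both on the Holocene base, so they sum to the total), and the
share of species that retain at least half of their Holocene range.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .periods import TimePeriod
from .reconstruction import RangeSet, proportion_lost

AREA_COLUMNS = [
    "area_hol_km2",
    "area_hist_km2",
    "area_mod_km2",
    "p_lost_hol_hist",
    "p_lost_hist_mod",
    "p_lost_hol_mod",
]


def area_table_from_ranges(
    ranges: dict[str, dict[TimePeriod, RangeSet]]
) -> pd.DataFrame:
    rows = {
        sp: {
            "area_hol_km2": by_period[TimePeriod.HOLOCENE].area_km2,
            "area_hist_km2": by_period[TimePeriod.HISTORICAL].area_km2,
            "area_mod_km2": by_period[TimePeriod.MODERN].area_km2,
        }
        for sp, by_period in ranges.items()
    }
    return area_table(pd.DataFrame.from_dict(rows, orient="index").rename_axis("species"))


def area_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Attach interval loss proportions to a three-column area table.

    ``areas`` is indexed by species with columns ``area_hol_km2``,
    ``area_hist_km2``, ``area_mod_km2``.  Species with a zero Holocene
    area are flagged with NaN proportions (loss undefined) rather than
    dropped.
    """
    out = areas.copy()
    for col, (old, new) in {
        "p_lost_hol_hist": ("area_hol_km2", "area_hist_km2"),
        "p_lost_hist_mod": ("area_hist_km2", "area_mod_km2"),
        "p_lost_hol_mod": ("area_hol_km2", "area_mod_km2"),
    }.items():
        out[col] = [
            proportion_lost(o, n) if o > 0 else float("nan")
            for o, n in zip(out[old], out[new])
        ]
    return out


def percent_remaining(areas: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Percentage of Holocene range remaining per later period, rounded.

    Display convention: a species with any nonzero loss never shows
    100%, and one with any nonzero remainder never shows 0% — values
    that would round across those endpoints are clamped to the nearest
    representable interior value (99.9 / 0.1 at one decimal), so the
    printed percentage is faithful to whether loss occurred at all.
    """
    step = 10.0**-ndigits
    out = {}
    for col, area_col in (
        ("pct_remaining_hist", "area_hist_km2"),
        ("pct_remaining_mod", "area_mod_km2"),
    ):
        pct = (100 * areas[area_col] / areas["area_hol_km2"]).round(ndigits)
        lossy = areas[area_col] < areas["area_hol_km2"]
        pct = pct.where(~(lossy & (pct >= 100.0)), 100.0 - step)
        some_left = areas[area_col] > 0
        pct = pct.where(~(some_left & (pct <= 0.0)), step)
        out[col] = pct
    return pd.DataFrame(out, index=areas.index)


@dataclass(frozen=True)
class AggregateSummary:
    pct_total_lost: float  # combined Holocene range lost by the present
    pct_lost_pre1900: float  # lost between the Holocene and historical layers
    pct_lost_post1900: float  # lost between the historical and modern layers
    pct_species_lost_lt50: float  # species retaining >= 50% of Holocene range
    n_species: int


def aggregate_summary(areas: pd.DataFrame) -> AggregateSummary:
    """Pool species areas into the fauna-wide loss percentages.

    All three loss percentages use the summed Holocene area as
    denominator, so pre- and post-1900 components add to the total.
    """
    a_hol = float(areas["area_hol_km2"].sum())
    a_hist = float(areas["area_hist_km2"].sum())
    a_mod = float(areas["area_mod_km2"].sum())
    if a_hol <= 0:
        raise ValueError("summed Holocene area is zero")
    frac_mod = areas["area_mod_km2"] / areas["area_hol_km2"]
    return AggregateSummary(
        pct_total_lost=100 * (a_hol - a_mod) / a_hol,
        pct_lost_pre1900=100 * (a_hol - a_hist) / a_hol,
        pct_lost_post1900=100 * (a_hist - a_mod) / a_hol,
        pct_species_lost_lt50=100 * float((frac_mod > 0.5).mean()),
        n_species=len(areas),
    )
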