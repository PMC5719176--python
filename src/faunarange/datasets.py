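"""Packaged reference datasets.

``load_china_mammal_ranges`` returns the published period areas (km^2)
for the 34 Chinese mammal species whose Holocene record meets the
10-site inclusion rule, with body masses and the percentage-remaining
columns as printed in the source compilation.  The areas are inputs to
the aggregate-accounting layer; the printed percentages serve as the
fixture for its arithmetic checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .areas import area_table


def load_china_mammal_ranges(with_printed: bool = False) -> pd.DataFrame:
    """Published three-period range areas for the 34-species fauna.

    Returns a species-indexed frame with ``body_mass_kg`` and the three
    ``area_*_km2`` columns plus derived interval loss proportions; with
    ``with_printed=True`` the percentage columns as printed in the
    source table are included (``pct_hist_printed``/``pct_mod_printed``).
    """
    with resources.files("faunarange.data").joinpath("china_mammal_ranges.csv").open() as fh:
        df = pd.read_csv(fh).set_index("species")
    out = area_table(df[["area_hol_km2", "area_hist_km2", "area_mod_km2"]])
    out.insert(0, "body_mass_kg", df["body_mass_kg"])
    if with_printed:
        out["pct_hist_printed"] = df["pct_hist_printed"]
        out["pct_mod_printed"] = df["pct_mod_printed"]
    return out
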