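"""Packaged worked example for the gap-analysis arithmetic.

A published island-wide gap analysis (57 reptile species/lineage range
maps against a 4-category zoning plan) provides per-feature cell counts,
statuses and representation targets; the numbers are shipped as package
data so the category-percent and target-achievement arithmetic can be
exercised and checked without any spatial inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: total island grid cells of the worked example
ISLAND_CELLS = 342_865
#: per-category totals of the worked example (categories 0..3)
CATEGORY_TOTALS = {0: 3213, 1: 88383, 2: 244795, 3: 6651}


def gap_fixture() -> pd.DataFrame:
    """Per-feature gap-analysis inputs.

    Columns: kind (species|lineage), status (IUCN code, blank for
    lineages), total range cells, target (%), cat0..cat3 cell counts, and
    a modelled flag (0 for the record-only taxa with <= 5 records).
    """
    with resources.files("evoreserve").joinpath("data/gap_fixture.csv").open() as fh:
        df = pd.read_csv(fh, index_col="feature", keep_default_na=False)
    df["modelled"] = df["modelled"].astype(bool)
    return df


def fixture_category_counts(feature: str) -> pd.Series:
    row = gap_fixture().loc[feature]
    return pd.Series({c: int(row[f"cat{c}"]) for c in range(4)}, name="cells")
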