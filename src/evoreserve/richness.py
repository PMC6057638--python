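"""Richness stacking, range-breadth partitions, hotspots and correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from evoreserve.raster import LandscapeStack
from evoreserve.sdm import BinaryRange

RESTRICTED_CUTOFF = 0.30


@dataclass
class RichnessLayer:
    definition: str  # e.g. "species_all", "lineage_restricted"
    count: np.ndarray  # integer per-cell feature count
    relative: np.ndarray  # 100 * count / max(count)

    @property
    def max_count(self) -> int:
        return int(self.count.max())


def classify_range_breadth(
    features: list[BinaryRange], n_island_cells: int, cutoff: float = RESTRICTED_CUTOFF
) -> tuple[list[BinaryRange], list[BinaryRange]]:
    """(wide, restricted): restricted iff range < cutoff * island area (strict)."""
    limit = cutoff * n_island_cells
    wide = [f for f in features if f.range_size >= limit]
    restricted = [f for f in features if f.range_size < limit]
    return wide, restricted


def stack_richness(features: list[BinaryRange], definition: str) -> RichnessLayer:
    if not features:
        raise ValueError(f"no features for richness layer {definition!r}")
    shape = features[0].raster.shape
    count = np.zeros(shape, dtype=int)
    for f in features:
        if f.raster.shape != shape:
            raise ValueError("feature rasters are not aligned")
        count += f.raster
    peak = count.max()
    relative = 100.0 * count / peak if peak > 0 else count.astype(float)
    return RichnessLayer(definition, count, relative)


def six_layers(
    species: list[BinaryRange], lineages: list[BinaryRange], n_island_cells: int
) -> dict[str, RichnessLayer]:
    """The standard {species,lineage} x {all,wide,restricted} layer set.

    Always returns exactly six layers; an empty feature class yields an
    all-zero layer.
    """
    shape = (species + lineages)[0].raster.shape
    out: dict[str, RichnessLayer] = {}
    for kind, feats in (("species", species), ("lineage", lineages)):
        wide, restricted = classify_range_breadth(feats, n_island_cells)
        for scope, sub in (("all", feats), ("wide", wide), ("restricted", restricted)):
            name = f"{kind}_{scope}"
            if sub:
                out[name] = stack_richness(sub, name)
            else:
                out[name] = RichnessLayer(name, np.zeros(shape, int), np.zeros(shape))
    return out


def difference_map(species_layer: RichnessLayer, lineage_layer: RichnessLayer) -> np.ndarray:
    """Relative-percent difference (species - lineage), in [-100, 100]."""
    if species_layer.relative.shape != lineage_layer.relative.shape:
        raise ValueError("richness layers are not aligned")
    return species_layer.relative - lineage_layer.relative


def top_quartile_binary(layer: RichnessLayer, mask: np.ndarray | None = None) -> np.ndarray:
    """Hotspot cells: relative richness at or above the 75th percentile.

    Percentile by the nearest-rank method over valid cells; threshold ties
    are included.
    """
    if mask is None:
        mask = np.ones(layer.relative.shape, dtype=bool)
    vals = np.sort(layer.relative[mask])
    if len(vals) == 0:
        raise ValueError("empty layer")
    rank = max(int(np.ceil(0.75 * len(vals))), 1)  # 1-based nearest rank
    threshold = vals[rank - 1]
    return (layer.relative >= threshold) & mask


def correlate_lv(
    layer: RichnessLayer, stack: LandscapeStack, include_coords: bool = True
) -> pd.DataFrame:
    """Pearson correlation of per-cell richness against each landscape
    variable (plus cell-centre latitude/longitude)."""
    mask = stack.mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 valid cells")
    y = layer.count[mask].astype(float)
    columns: dict[str, np.ndarray] = {}
    if include_coords:
        x, yy = stack.grid.coord_arrays()
        columns["lat"] = yy[mask]
        columns["lon"] = x[mask]
    for name in stack.var_names:
        columns[name] = stack.layers[name][mask]
    rows = []
    for name, v in columns.items():
        if np.std(v) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan))
            continue
        rho, p = stats.pearsonr(y, v)
        rows.append((name, rho, p))
    return pd.DataFrame(rows, columns=["variable", "rho", "p_value"]).set_index("variable")
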