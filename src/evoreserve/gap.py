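"""Gap analysis: representation of features and hotspots in a zoning plan.

The zoning plan is a categorical raster with values 0-3 (0 = general use,
1 = resource use, 2 = national park, 3 = sanctuaries); categories 1-3 are
Protected Areas.  Representation targets are interpolated log-linearly
between 10% for the widest-ranging feature and 100% for the narrowest,
with status adjustments (CR -> 100, DD -> +30 capped at 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from evoreserve.richness import RichnessLayer
from evoreserve.sdm import BinaryRange

PA_CATEGORIES = (1, 2, 3)
CATEGORIES = (0, 1, 2, 3)


@dataclass
class ZoningPlan:
    """Categorical protection raster; -1 marks cells outside the island."""

    categories: np.ndarray

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=int)
        vals = np.unique(self.categories)
        if not np.isin(vals, [-1, 0, 1, 2, 3]).all():
            raise ValueError(f"zoning categories must be in 0..3, got {vals}")

    @property
    def mask(self) -> np.ndarray:
        return self.categories >= 0

    @property
    def pa_mask(self) -> np.ndarray:
        return np.isin(self.categories, PA_CATEGORIES)


def category_counts(feature: BinaryRange | np.ndarray, zp: ZoningPlan) -> pd.Series:
    """Cells of a feature's range per zoning category (a partition of it)."""
    raster = feature.raster if isinstance(feature, BinaryRange) else np.asarray(feature, bool)
    if raster.shape != zp.categories.shape:
        raise ValueError("feature and zoning plan grids differ")
    if not raster.any():
        raise ValueError("empty feature range")
    cats = zp.categories[raster]
    return pd.Series({c: int((cats == c).sum()) for c in CATEGORIES}, name="cells")


def category_percents(counts: pd.Series) -> pd.Series:
    return 100.0 * counts / counts.sum()


def representation_target(
    range_cells: int,
    a_min: float,
    a_max: float,
    status: str = "LC",
    scale: str = "loglog",
    modelled: bool = True,
) -> float:
    """Range-size dependent representation target in percent.

    Default ``loglog``: ln(target) falls linearly in ln(area) from 100% at
    the narrowest range (a_min) to 10% at the widest (a_max); the
    alternative ``linear-in-logA`` interpolates the target itself linearly
    in ln(area).  Status rules: CR -> 100; DD -> +30 capped at 100;
    non-modelled features -> 100.
    """
    if a_max <= a_min:
        raise ValueError("a_max must exceed a_min")
    if not a_min <= range_cells:
        raise ValueError("range_cells below a_min")
    if not modelled or status == "CR":
        return 100.0
    ratio = np.log(range_cells / a_min) / np.log(a_max / a_min)
    if scale == "loglog":
        target = float(np.exp(np.log(100.0) - np.log(10.0) * ratio))
    elif scale == "linear-in-logA":
        target = float(100.0 + (10.0 - 100.0) * ratio)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    target = float(np.clip(target, 10.0, 100.0))
    if status == "DD":
        target = min(target + 30.0, 100.0)
    return target


def target_achievement(counts: pd.Series, target: float) -> float:
    """100 * (PA share of the range) / (target share)."""
    if target <= 0:
        raise ValueError("target must be positive")
    pa = sum(counts[c] for c in PA_CATEGORIES)
    return 100.0 * (pa / counts.sum()) / (target / 100.0)


def is_protected(counts: pd.Series, target: float) -> bool:
    pa_percent = 100.0 * sum(counts[c] for c in PA_CATEGORIES) / counts.sum()
    return pa_percent >= target


def richness_gap(hotspot: np.ndarray, zp: ZoningPlan) -> float:
    """Percent of hotspot cells inside Protected Areas (target is 100%)."""
    hotspot = np.asarray(hotspot, bool)
    n = hotspot.sum()
    if n == 0:
        raise ValueError("empty hotspot")
    return 100.0 * float((hotspot & zp.pa_mask).sum()) / float(n)


def compare_in_out(layer: RichnessLayer, zp: ZoningPlan) -> dict:
    """Poisson GLM of per-cell richness on a PA indicator.

    Returns per-group means with Wald 95% confidence intervals and the
    two-sided p-value of the group contrast.
    """
    mask = zp.mask
    inside = zp.pa_mask[mask]
    y = layer.count[mask].astype(float)
    if not inside.any() or inside.all():
        raise ValueError("need cells both inside and outside PAs")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance richness response")
    X = sm.add_constant(inside.astype(float))
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    # group means on the response scale, with Wald CIs transformed from the
    # linear predictor
    params = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params())
    out = {}
    for name, x in (("outside", 0.0), ("inside", 1.0)):
        eta = params[0] + params[1] * x
        se = np.sqrt(cov[0, 0] + x**2 * cov[1, 1] + 2 * x * cov[0, 1])
        out[name] = {
            "mean": float(np.exp(eta)),
            "ci": (float(np.exp(eta - 1.96 * se)), float(np.exp(eta + 1.96 * se))),
        }
    out["p_value"] = float(np.asarray(fit.pvalues)[1])
    return out


def gap_table(
    features: list[BinaryRange],
    zp: ZoningPlan,
    targets: dict[str, float] | None = None,
    target_scale: str = "loglog",
    modelled_min_records: int = 6,
) -> pd.DataFrame:
    """Per-feature gap-analysis table.

    When explicit ``targets`` are not given they are derived from the range
    sizes of the modelled features (endpoints = their min/max range).
    """
    island = int(zp.mask.sum())
    sizes = {f.feature_id: f.range_size for f in features}
    modelled = {fid: s for fid, s in sizes.items() if s >= modelled_min_records}
    rows = []
    for f in features:
        counts = category_counts(f, zp)
        if targets is not None:
            tau = targets[f.feature_id]
        elif modelled:
            tau = representation_target(
                max(f.range_size, min(modelled.values())),
                min(modelled.values()),
                max(modelled.values()),
                status=f.status,
                scale=target_scale,
                modelled=f.feature_id in modelled,
            )
        else:
            tau = 100.0
        pct = category_percents(counts)
        rows.append(
            {
                "feature": f.feature_id,
                "kind": f.kind,
                "status": f.status,
                "total": f.range_size,
                "range_percent": 100.0 * f.range_size / island,
                "target_percent": tau,
                **{f"cat{c}_cells": counts[c] for c in CATEGORIES},
                **{f"cat{c}_percent": pct[c] for c in CATEGORIES},
                "achievement": target_achievement(counts, tau),
                "protected": is_protected(counts, tau),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
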