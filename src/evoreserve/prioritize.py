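"""Target-based greedy reverse-removal reserve prioritization.

Starting from the full landscape, edge cells are removed one (or ``warp``)
at a time in order of a removal score combining each feature's marginal
representation loss, a boundary-length term encouraging aggregation, and
the cell cost; removals that would push any feature below its target are
forbidden.  The cells remaining when no removal is feasible form the
minimal set; ranking then continues without targets to a full ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from evoreserve.gap import CATEGORIES, ZoningPlan
from evoreserve.sdm import BinaryRange

EPS = 1e-9
_N8 = np.ones((3, 3), dtype=int)
_N4 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=int)


def build_cost(
    zp: ZoningPlan,
    cellsize: float = 1.0,
    main_roads: np.ndarray | None = None,
    urban: np.ndarray | None = None,
    secondary_roads: np.ndarray | None = None,
    road_buffer: float = 112.0,
    urban_buffer: float = 1000.0,
    category_costs: dict[int, float] | None = None,
) -> np.ndarray:
    """Cost raster: per-cell maximum of all applicable cost rules.

    Base costs by zoning category (general/resource use 50, national park
    25, sanctuary 1); cells within the buffer of main roads or urban areas
    cost 100, within secondary roads 50.  Buffers are radii in map units.
    """
    cc = dict({0: 50.0, 1: 50.0, 2: 25.0, 3: 1.0}, **(category_costs or {}))
    cost = np.ones(zp.categories.shape)
    for cat, c in cc.items():
        cost[zp.categories == cat] = c

    def apply_buffer(mask_arr: np.ndarray | None, radius: float, value: float) -> None:
        if mask_arr is None or not np.asarray(mask_arr, bool).any():
            return
        dist = ndimage.distance_transform_edt(~np.asarray(mask_arr, bool)) * cellsize
        np.maximum(cost, np.where(dist <= radius, value, 0.0), out=cost)

    apply_buffer(main_roads, road_buffer, 100.0)
    apply_buffer(urban, urban_buffer, 100.0)
    apply_buffer(secondary_roads, road_buffer, 50.0)
    cost[~zp.mask] = np.nan
    return cost


@dataclass
class PrioritizationProblem:
    features: list[BinaryRange]
    targets: dict[str, float]  # percent of each feature's range to retain
    cost: np.ndarray
    mask: np.ndarray
    blp: float = 0.4
    warp: int = 1

    def __post_init__(self) -> None:
        for f in self.features:
            if f.raster.shape != self.mask.shape:
                raise ValueError("feature rasters not aligned with the mask")
            tau = self.targets.get(f.feature_id)
            if tau is None or not (0 < tau <= 100):
                raise ValueError(f"feature {f.feature_id!r} needs a target in (0, 100]")


@dataclass
class PrioritizationResult:
    rank: np.ndarray  # 1 = removed first; minimal-set cells have highest ranks
    minimal: np.ndarray  # bool minimal-set raster
    trace: pd.DataFrame  # iteration, row, col, score, per-feature representation
    termination: str
    feature_ids: list[str] = field(default_factory=list)


def edge_cells(included: np.ndarray) -> np.ndarray:
    """Included cells with >=1 excluded 8-neighbour (raster border counts)."""
    inc = included.astype(int)
    full = ndimage.correlate(inc, _N8, mode="constant", cval=0)
    return included & (full < 9)


def boundary_delta(included: np.ndarray) -> np.ndarray:
    """Change in total 4-neighbourhood boundary length if a cell is removed."""
    inc = included.astype(int)
    k_in = ndimage.correlate(inc, _N4, mode="constant", cval=0)
    return 2.0 * k_in - 4.0


def removal_scores(
    included: np.ndarray,
    candidates: np.ndarray,
    feature_rasters: np.ndarray,
    rep: np.ndarray,
    tau: np.ndarray,
    sizes: np.ndarray,
    cost: np.ndarray,
    blp: float,
) -> np.ndarray:
    """Score (lower = removed earlier) for each candidate cell.

    score = [max_f p_f / max(R_f - tau_f, eps) + blp * dL/4] / cost, with
    p_f the cell's share (1/|range_f|) of feature f.
    """
    slack = np.maximum(rep - tau, EPS)
    loss = np.zeros(included.shape)
    for f in range(len(feature_rasters)):
        v = (1.0 / sizes[f]) / slack[f]
        np.maximum(loss, np.where(feature_rasters[f], v, 0.0), out=loss)
    dl = boundary_delta(included)
    scores = (loss + blp * dl / 4.0) / cost
    return np.where(candidates, scores, np.inf)


def rank_cells(problem: PrioritizationProblem, record_trace: bool = True) -> PrioritizationResult:
    """Greedy reverse removal to a full ranking with minimal-set extraction."""
    mask = problem.mask
    n_cells = int(mask.sum())
    feats = np.stack([f.raster & mask for f in problem.features])
    sizes = feats.reshape(len(feats), -1).sum(axis=1).astype(float)
    ids = [f.feature_id for f in problem.features]
    empty = [i for i, s in zip(ids, sizes) if s == 0]
    if empty:
        raise ValueError(f"features with empty ranges cannot meet targets: {empty}")
    tau = np.array([problem.targets[i] / 100.0 for i in ids])

    included = mask.copy()
    counts = sizes.copy()  # included cells per feature
    rank = np.zeros(mask.shape, dtype=int)
    cost = np.where(np.isfinite(problem.cost), problem.cost, 1.0)
    trace_rows = []
    minimal = None
    next_rank = 1
    iteration = 0
    targets_active = True

    while next_rank <= n_cells:
        iteration += 1
        rep = counts / sizes
        cand = edge_cells(included)
        if targets_active:
            # a feature is frozen when losing any one of its cells violates
            # its target; all its cells leave the candidate set
            frozen = (rep - 1.0 / sizes) < tau - 1e-12
            if frozen.any():
                cand &= ~feats[frozen].any(axis=0)
            if not cand.any():
                minimal = included.copy()
                targets_active = False
                continue
        if not cand.any():  # pragma: no cover - defensive; cannot occur
            break
        scores = removal_scores(
            included, cand, feats, rep, tau, sizes, cost, problem.blp
        )
        order = np.argsort(scores, axis=None, kind="stable")
        removed_this_iter = 0
        for flat in order:
            if removed_this_iter >= problem.warp or not np.isfinite(scores.flat[flat]):
                break
            r, c = np.unravel_index(flat, mask.shape)
            if not cand[r, c]:
                continue
            hit = feats[:, r, c]
            if targets_active and ((counts - hit) / sizes < tau - 1e-12)[hit].any():
                continue
            included[r, c] = False
            counts = counts - hit
            rank[r, c] = next_rank
            if record_trace:
                trace_rows.append(
                    {
                        "iteration": iteration,
                        "row": int(r),
                        "col": int(c),
                        "score": float(scores[r, c]),
                        **{f"R_{i}": counts[j] / sizes[j] for j, i in enumerate(ids)},
                    }
                )
            next_rank += 1
            removed_this_iter += 1
        if removed_this_iter == 0:
            if targets_active:
                minimal = included.copy()
                targets_active = False
                continue
            break  # pragma: no cover - defensive

    if minimal is None:  # every cell was removable: minimal set is empty
        minimal = included.copy()
    termination = "complete" if next_rank > n_cells else "stalled"
    trace = pd.DataFrame(trace_rows)
    return PrioritizationResult(rank, minimal, trace, termination, ids)


def minimal_set(result: PrioritizationResult, feature_id: str = "solution") -> BinaryRange:
    return BinaryRange(feature_id, "solution", result.minimal)


def verify_targets(
    result: PrioritizationResult, problem: PrioritizationProblem
) -> pd.Series:
    """Representation of each feature within the minimal set (fraction)."""
    out = {}
    for f in problem.features:
        size = int((f.raster & problem.mask).sum())
        out[f.feature_id] = float((f.raster & result.minimal).sum()) / size
    return pd.Series(out, name="representation")


def compare_solutions(
    sol_a: np.ndarray, sol_b: np.ndarray, zp: ZoningPlan
) -> dict:
    """Per-category composition of two solutions and a Pearson chi-square.

    The 2x4 count table (solution x zoning category) gives df = 3.
    """
    rows = {}
    for name, sol in (("A", sol_a), ("B", sol_b)):
        sol = np.asarray(sol, bool)
        if not sol.any():
            raise ValueError(f"solution {name} is empty")
        cats = zp.categories[sol]
        rows[name] = [int((cats == c).sum()) for c in CATEGORIES]
    table = pd.DataFrame(rows, index=[f"cat{c}" for c in CATEGORIES]).T
    counts = table.to_numpy()
    keep = counts.sum(axis=0) > 0  # drop all-zero categories to keep E > 0
    chi2, p, dof, _ = stats.chi2_contingency(counts[:, keep], correction=False)
    percents = 100.0 * table.div(table.sum(axis=1), axis=0)
    return {
        "counts": table,
        "percents": percents,
        "chi2": float(chi2),
        "df": int(dof),
        "p_value": float(p),
    }
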