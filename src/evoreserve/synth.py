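"""Synthetic inputs with known ground truth.

Generators for every input the pipeline consumes: correlated random-field
landscapes, virtual species with spatially partitioned lineages, occurrence
samples, mixed Yule/coalescent ultrametric trees, distance-plus-offset
genetic matrices and categorical zoning plans.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from evoreserve.raster import Grid, LandscapeStack
from evoreserve.trees import UltrametricTree


@dataclass
class TruthSet:
    """Ground truth for one virtual species.

    ``suitability`` is the true suitability surface in [0, 1]; ``domains``
    labels each true-range cell with its lineage (0-based) and is -1
    elsewhere; ``cutoff`` is the suitability level defining the true range.
    """

    stack: LandscapeStack
    suitability: np.ndarray
    domains: np.ndarray
    cutoff: float
    params: dict = field(default_factory=dict)

    @property
    def n_lineages(self) -> int:
        labels = self.domains[self.domains >= 0]
        return int(labels.max()) + 1 if labels.size else 0

    @property
    def range_mask(self) -> np.ndarray:
        return self.domains >= 0


def gen_landscape(seed: int, nrows: int, ncols: int, n_vars: int, autocorr_range: float = 4.0) -> LandscapeStack:
    """Stack of standardized Gaussian random-field layers.

    Each layer is white noise smoothed with a Gaussian kernel of scale
    ``autocorr_range`` (in cells); a range of 0 gives uncorrelated noise.
    """
    if nrows < 8 or ncols < 8:
        raise ValueError("grid must be at least 8x8")
    if n_vars < 2:
        raise ValueError("need at least 2 landscape variables")
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be nonnegative")
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}
    for v in range(n_vars):
        z = rng.standard_normal((nrows, ncols))
        if autocorr_range > 0:
            z = gaussian_filter(z, sigma=autocorr_range, mode="wrap")
        z = (z - z.mean()) / z.std()
        layers[f"lv{v:02d}"] = z
    return LandscapeStack(Grid(nrows, ncols), layers)


def logistic_response(var: str, center: float = 0.0, slope: float = 2.0):
    """Convenience response: logistic suitability in one landscape variable."""

    def response(stack: LandscapeStack) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-slope * (stack.layers[var] - center)))

    return response


def gen_virtual_species(
    stack: LandscapeStack,
    response,
    n_lineages: int,
    seed: int,
    cutoff: float = 0.3,
) -> TruthSet:
    """Virtual species: suitability = response(LVs); lineages = Voronoi domains.

    Lineage domains are a contiguous spatial partition of the true range
    (cells with suitability above ``cutoff``), obtained by nearest-seed
    assignment around ``n_lineages`` random range cells.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    suit = np.clip(np.asarray(response(stack), dtype=float), 0.0, 1.0)
    if suit.shape != stack.grid.shape:
        raise ValueError("response must return a raster matching the grid")
    suit = np.where(stack.mask, suit, 0.0)
    range_mask = (suit > cutoff) & stack.mask
    rr, cc = np.nonzero(range_mask)
    if len(rr) < n_lineages:
        raise ValueError(f"true range has {len(rr)} cells, fewer than {n_lineages} lineages")
    rng = np.random.default_rng(seed)
    domains = np.full(stack.grid.shape, -1, dtype=int)
    if n_lineages == 1:
        domains[range_mask] = 0
    else:
        seeds = rng.choice(len(rr), size=n_lineages, replace=False)
        sr, sc = rr[seeds], cc[seeds]
        d2 = (rr[:, None] - sr[None, :]) ** 2 + (cc[:, None] - sc[None, :]) ** 2
        domains[rr, cc] = np.argmin(d2, axis=1)
    return TruthSet(stack, suit, domains, cutoff, params={"n_lineages": n_lineages, "seed": seed})


def sample_occurrences(truth: TruthSet, n: int, seed: int, feature_id: str = "sp") -> pd.DataFrame:
    """Presence records sampled without replacement, weighted by suitability.

    Cells with positive suitability are sampled with probability
    proportional to suitability (one record per cell); coordinates are cell
    centres and each record carries the true lineage of its cell (nearest
    domain for cells just outside the range cutoff).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rr, cc = np.nonzero((truth.suitability > 0) & truth.stack.mask)
    w = truth.suitability[rr, cc]
    if n > len(rr):
        raise ValueError(f"requested {n} records but only {len(rr)} candidate cells")
    # weighted sampling without replacement via exponential sort keys
    keys = rng.exponential(size=len(rr)) / w
    take = np.argsort(keys, kind="stable")[:n]
    rows, cols = rr[take], cc[take]
    lon, lat = truth.stack.grid.cell_center(rows, cols)
    lineage = truth.domains[rows, cols].astype(float)
    if (lineage < 0).any() and truth.n_lineages:
        dr, dc = np.nonzero(truth.domains >= 0)
        for i in np.flatnonzero(lineage < 0):
            j = np.argmin((dr - rows[i]) ** 2 + (dc - cols[i]) ** 2)
            lineage[i] = truth.domains[dr[j], dc[j]]
    return pd.DataFrame(
        {
            "feature_id": feature_id,
            "lon": lon,
            "lat": lat,
            "lineage": lineage.astype(int),
            "row": rows,
            "col": cols,
        }
    )


# ---------------------------------------------------------------------------
# trees


def _coalescent_nested(n_tips: int, scale: float, rng: np.random.Generator, tip_ids: list):
    """Kingman coalescent as a nested (height, children) structure."""
    active: list = [("tip", t, 0.0) for t in tip_ids]
    heights = {id(a): 0.0 for a in active}
    t = 0.0
    nodes = list(active)
    while len(nodes) > 1:
        j = len(nodes)
        t += rng.exponential(scale / (j * (j - 1) / 2.0))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = nodes[i1], nodes[i2]
        merged = ("node", t, [a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i1, i2)] + [merged]
    return nodes[0]


def _nested_height(node) -> float:
    return 0.0 if node[0] == "tip" else node[1]


def _rescale_nested(node, factor: float):
    if node[0] == "tip":
        return node
    return ("node", node[1] * factor, [_rescale_nested(c, factor) for c in node[2]])


def _yule_nested(n_tips: int, rate: float, rng: np.random.Generator, subtrees: list):
    """Yule tree over ``n_tips`` lineages; leaves replaced by ``subtrees``.

    Forward simulation: each active lineage splits at rate ``rate``; an
    extra exponential hold after the n-th birth sets the present.  Leaf i
    of the Yule tree is grafted onto subtree i (its root hung on the
    pendant branch; subtrees too deep for their branch are rescaled).
    """
    if n_tips == 1:
        return subtrees[0]
    # events: list of (time, lineage, left_child, right_child); lineages are ints
    events = []
    active = [0]
    nxt = 1
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (rate * len(active)))
        k = int(rng.integers(len(active)))
        lin = active.pop(k)
        events.append((t, lin, nxt, nxt + 1))
        active += [nxt, nxt + 1]
        nxt += 2
    present = t + rng.exponential(1.0 / (rate * n_tips))
    split_of = {lin: (tm, a, b) for tm, lin, a, b in events}
    leaf_assign = {lin: i for i, lin in enumerate(active)}

    def build(lin: int, parent_height: float):
        if lin in split_of:
            tm, a, b = split_of[lin]
            h = present - tm
            return ("node", h, [build(a, h), build(b, h)])
        sub = subtrees[leaf_assign[lin]]
        h = _nested_height(sub)
        if h >= parent_height:
            sub = _rescale_nested(sub, 0.5 * parent_height / h)
        return sub

    tm0, a0, b0 = split_of[0]
    h0 = present - tm0
    return ("node", h0, [build(a0, h0), build(b0, h0)])


def _flatten_nested(root) -> tuple[np.ndarray, np.ndarray, list[str]]:
    tips: list = []
    internals: list = []

    def collect(node):
        if node[0] == "tip":
            tips.append(node)
        else:
            internals.append(node)
            for c in node[2]:
                collect(c)

    collect(root)
    index: dict[int, int] = {}
    for i, nd in enumerate(tips):
        index[id(nd)] = i
    for j, nd in enumerate(internals):
        index[id(nd)] = len(tips) + j
    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=int)
    heights = np.zeros(n)
    for nd in internals:
        heights[index[id(nd)]] = nd[1]
        for c in nd[2]:
            parent[index[id(c)]] = index[id(nd)]
    if root[0] == "tip":  # degenerate single-tip tree
        heights[:] = 0.0
    labels = [nd[1] for nd in tips]
    return parent, heights, labels


def gen_tree(
    n_clusters: int,
    tips_per_cluster: int,
    yule_rate: float = 1.0,
    coal_scale: float = 0.05,
    seed: int = 0,
) -> tuple[UltrametricTree, pd.Series]:
    """Ultrametric tree: Yule between clusters, coalescent within.

    Returns the tree and the true assignment (tip label -> cluster index).
    With ``tips_per_cluster=1`` the tree is pure Yule; with ``n_clusters=1``
    pure coalescent.
    """
    if n_clusters < 1 or tips_per_cluster < 1:
        raise ValueError("n_clusters and tips_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    subtrees = []
    assignment: dict[str, int] = {}
    for c in range(n_clusters):
        labels = [f"c{c}_t{i}" for i in range(tips_per_cluster)]
        for lb in labels:
            assignment[lb] = c
        subtrees.append(_coalescent_nested(tips_per_cluster, coal_scale, rng, labels))
    root = _yule_nested(n_clusters, yule_rate, rng, subtrees)
    parent, heights, tip_labels = _flatten_nested(root)
    tree = UltrametricTree(parent, heights, tip_labels)
    tree.validate()
    return tree, pd.Series(assignment, name="cluster")


# ---------------------------------------------------------------------------
# genetic distances


def gen_genetic_distances(
    samples: pd.DataFrame,
    within_rate: float = 0.01,
    between_offset: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise genetic distances: isolation-by-distance plus lineage offset.

    d(i, j) = within_rate * ||x_i - x_j|| + between_offset * [lineage_i !=
    lineage_j] + |eps_ij|; symmetric, hollow, nonnegative by construction.
    ``samples`` needs columns lon, lat, lineage.
    """
    rng = np.random.default_rng(seed)
    xy = samples[["lon", "lat"]].to_numpy(float)
    lin = samples["lineage"].to_numpy()
    n = len(samples)
    geo = np.hypot(xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1])
    diff = (lin[:, None] != lin[None, :]).astype(float)
    d = within_rate * geo + between_offset * diff
    if noise_sd > 0:
        eps = np.abs(rng.normal(0.0, noise_sd, size=(n, n)))
        eps = np.triu(eps, k=1)
        d = d + eps + eps.T
    np.fill_diagonal(d, 0.0)
    ids = samples.index.astype(str)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# zoning


DEFAULT_COST_RULES = {0: 50.0, 1: 50.0, 2: 25.0, 3: 1.0}


def gen_zoning(
    stack: LandscapeStack,
    category_fractions=(0.25, 0.25, 0.25, 0.25),
    cost_rules: dict[int, float] | None = None,
    seed: int = 0,
    patch_scale: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Zoning plan (categories 0-3 in contiguous patches) and a cost raster.

    A smooth random field is cut at the cumulative-fraction quantiles so
    category areas match the requested fractions; the cost raster maps the
    base cost of each category (general/resource use 50, national park 25,
    sanctuary 1 by default).  Masked cells are -1 in the plan.
    """
    fracs = np.asarray(category_fractions, dtype=float)
    if len(fracs) != 4 or fracs.min() < 0 or abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError("category_fractions must be 4 nonnegative values summing to 1")
    rules = dict(DEFAULT_COST_RULES if cost_rules is None else cost_rules)
    rng = np.random.default_rng(seed)
    grid = stack.grid
    sigma = patch_scale if patch_scale is not None else max(2.0, min(grid.nrows, grid.ncols) / 8.0)
    field_ = gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma, mode="wrap")
    vals = field_[stack.mask]
    cum = np.cumsum(fracs)[:-1]
    cuts = np.quantile(vals, cum)
    zp = np.full(grid.shape, -1, dtype=int)
    zp[stack.mask] = np.digitize(field_[stack.mask], cuts)
    cost = np.ones(grid.shape)
    for cat, c in rules.items():
        cost[zp == cat] = c
    cost[~stack.mask] = np.nan
    return zp, cost
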