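from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from evoreserve import gap, prioritize
from evoreserve.sdm import BinaryRange


def make_problem(feature_cells, targets, shape=(6, 6), blp=0.0, cost=None, warp=1):
    mask = np.ones(shape, bool)
    feats = []
    for fid, cells in feature_cells.items():
        raster = np.zeros(shape, bool)
        for r, c in cells:
            raster[r, c] = True
        feats.append(BinaryRange(fid, "species", raster))
    if cost is None:
        cost = np.ones(shape)
    return prioritize.PrioritizationProblem(feats, targets, cost, mask, blp=blp, warp=warp)


def brute_force_min_set(feature_cells, targets, shape):
    """Oracle: smallest cell subset meeting every target, by exhaustive search."""
    cells = [(r, c) for r in range(shape[0]) for c in range(shape[1])]
    needed = {
        fid: int(np.ceil(targets[fid] / 100.0 * len(fc) - 1e-9))
        for fid, fc in feature_cells.items()
    }
    for size in range(0, len(cells) + 1):
        for subset in combinations(cells, size):
            s = set(subset)
            if all(len(s & set(fc)) >= needed[fid] for fid, fc in feature_cells.items()):
                return size
    return len(cells)


class TestBuildCost:
    def _zp(self):
        cats = np.zeros((8, 8), dtype=int)
        cats[:, 2:4] = 1
        cats[:, 4:6] = 2
        cats[:, 6:] = 3
        return gap.ZoningPlan(cats)

    def test_base_costs(self):
        cost = prioritize.build_cost(self._zp())
        assert cost[0, 0] == 50.0  # general use
        assert cost[0, 2] == 50.0  # resource use
        assert cost[0, 4] == 25.0  # national park
        assert cost[0, 6] == 1.0  # sanctuary

    def test_road_buffer_overrides_park(self):
        roads = np.zeros((8, 8), bool)
        roads[0, 4] = True
        cost = prioritize.build_cost(self._zp(), cellsize=100.0, main_roads=roads, road_buffer=112.0)
        assert cost[0, 4] == 100.0
        assert cost[1, 4] == 100.0  # 100 m away, inside the 112 m buffer
        assert cost[2, 4] == 25.0  # 200 m away, outside

    def test_sanctuary_with_urban_buffer(self):
        urban = np.zeros((8, 8), bool)
        urban[0, 7] = True
        cost = prioritize.build_cost(self._zp(), cellsize=500.0, urban=urban, urban_buffer=1000.0)
        assert cost[0, 7] == 100.0
        assert cost[2, 7] == 100.0  # 1000 m
        assert cost[3, 7] == 1.0


class TestEdgeAndBoundary:
    def test_border_counts_as_excluded(self):
        included = np.ones((4, 4), bool)
        edges = prioritize.edge_cells(included)
        inner = np.zeros((4, 4), bool)
        inner[1:3, 1:3] = True
        assert np.array_equal(edges, ~inner)

    def test_boundary_delta(self):
        included = np.ones((3, 3), bool)
        dl = prioritize.boundary_delta(included)
        assert dl[1, 1] == 4.0  # interior: removal creates a hole
        assert dl[0, 1] == 2.0  # edge with 3 included neighbours
        assert dl[0, 0] == 0.0  # corner with 2


class TestRemovalScores:
    def test_higher_cost_removed_first(self):
        prob = make_problem({"f": [(0, 0)]}, {"f": 100.0}, shape=(3, 3))
        cost = np.ones((3, 3))
        cost[2, 2] = 100.0
        included = np.ones((3, 3), bool)
        cand = prioritize.edge_cells(included)
        feats = np.stack([f.raster for f in prob.features])
        scores = prioritize.removal_scores(
            included, cand, feats, np.array([1.0]), np.array([1.0]), np.array([1.0]), cost, blp=0.4
        )
        assert scores[2, 2] < scores[2, 1]

    def test_featureless_cells_score_lowest(self):
        prob = make_problem({"f": [(1, 1)]}, {"f": 50.0}, shape=(3, 3))
        included = np.ones((3, 3), bool)
        cand = prioritize.edge_cells(included)
        feats = np.stack([f.raster for f in prob.features])
        scores = prioritize.removal_scores(
            included, cand, feats, np.array([1.0]), np.array([0.5]), np.array([1.0]),
            np.ones((3, 3)), blp=0.4,
        )
        finite = scores[np.isfinite(scores)]
        # (1,1) holds the only feature; it is not even a candidate (not on edge)
        assert np.isinf(scores[1, 1])
        assert finite.min() < 1.0


class TestRankCells:
    def test_single_feature_full_target(self):
        cells = [(2, 2), (2, 3), (3, 2)]
        prob = make_problem({"f": cells}, {"f": 100.0})
        res = prioritize.rank_cells(prob)
        assert {tuple(x) for x in np.argwhere(res.minimal)} == set(cells)

    def test_half_target_size_oracle(self):
        cells = [(r, c) for r in range(6) for c in range(6)]
        prob = make_problem({"f": cells}, {"f": 50.0})
        res = prioritize.rank_cells(prob)
        assert res.minimal.sum() == 18  # ceil(50% of 36)

    def test_minimal_set_meets_targets_and_is_locally_minimal(self):
        feature_cells = {
            "a": [(0, 0), (0, 1), (1, 0), (1, 1)],
            "b": [(2, 2), (2, 3), (3, 2), (3, 3)],
        }
        targets = {"a": 50.0, "b": 50.0}
        prob = make_problem(feature_cells, targets, shape=(4, 4))
        res = prioritize.rank_cells(prob)
        rep = prioritize.verify_targets(res, prob)
        assert (rep >= 0.5 - 1e-9).all()
        # local minimality: no remaining cell is removable without violation
        for r, c in np.argwhere(res.minimal):
            ok = True
            for f in prob.features:
                if f.raster[r, c]:
                    size = f.raster.sum()
                    kept = (f.raster & res.minimal).sum() - 1
                    if kept / size < targets[f.feature_id] / 100.0 - 1e-12:
                        ok = False
            assert not ok, f"cell ({r},{c}) is removable"

    def test_rank_is_permutation(self):
        prob = make_problem({"f": [(0, 0), (5, 5)]}, {"f": 100.0})
        res = prioritize.rank_cells(prob)
        ranks = res.rank[res.rank > 0]
        n_removed = 36 - res.minimal.sum() + (res.rank[res.minimal] > 0).sum()
        assert sorted(ranks) == list(range(1, 37))

    def test_minimal_cells_ranked_last(self):
        prob = make_problem({"f": [(1, 1), (1, 2), (4, 4)]}, {"f": 100.0})
        res = prioritize.rank_cells(prob)
        assert res.rank[res.minimal].min() > res.rank[~res.minimal].max()

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            prob = make_problem({"f": []}, {"f": 50.0})
            prioritize.rank_cells(prob)

    def test_target_monotonicity(self):
        feature_cells = {"f": [(r, c) for r in range(4) for c in range(4)]}
        sizes = []
        for tau in (25.0, 50.0, 75.0):
            prob = make_problem(feature_cells, {"f": tau}, shape=(5, 5))
            sizes.append(int(prioritize.rank_cells(prob).minimal.sum()))
        assert sizes == sorted(sizes)

    def test_blp_reduces_perimeter_ratio(self):
        rng = np.random.default_rng(0)
        raster_cells = [(r, c) for r in range(8) for c in range(8) if rng.random() < 0.7]
        ratios = {}
        for blp in (0.0, 0.4):
            prob = make_problem({"f": raster_cells}, {"f": 60.0}, shape=(8, 8), blp=blp)
            res = prioritize.rank_cells(prob)
            area = res.minimal.sum()
            k_in = prioritize.boundary_delta(res.minimal)
            perim = (4.0 - (k_in + 4.0) / 2.0)[res.minimal].sum()
            ratios[blp] = perim / area
        assert ratios[0.4] <= ratios[0.0] + 1e-9

    def test_greedy_within_one_of_bruteforce(self):
        cases = [
            ({"a": [(0, 0), (0, 1), (1, 1)], "b": [(2, 2), (3, 3)]}, {"a": 67.0, "b": 50.0}),
            (
                {
                    "a": [(0, 0), (1, 1), (2, 2), (3, 3)],
                    "b": [(0, 3), (1, 2), (2, 1)],
                    "c": [(0, 0), (0, 3)],
                },
                {"a": 50.0, "b": 34.0, "c": 50.0},
            ),
            ({"a": [(r, c) for r in range(2) for c in range(4)]}, {"a": 75.0}),
        ]
        for feature_cells, targets in cases:
            prob = make_problem(feature_cells, targets, shape=(4, 4))
            res = prioritize.rank_cells(prob)
            greedy = int(res.minimal.sum())
            optimum = brute_force_min_set(feature_cells, targets, (4, 4))
            assert greedy <= optimum + 1

    def test_warp_removes_multiple(self):
        prob = make_problem({"f": [(0, 0)]}, {"f": 100.0}, warp=4)
        res = prioritize.rank_cells(prob)
        assert res.trace["iteration"].value_counts().max() <= 4
        assert res.minimal.sum() == 1


class TestMinimalSetAndCompare:
    def test_minimal_set_subset_of_feature_union_beta0(self):
        feature_cells = {"a": [(0, 0), (0, 1)], "b": [(3, 3), (3, 4)]}
        prob = make_problem(feature_cells, {"a": 100.0, "b": 50.0}, shape=(5, 5), blp=0.0)
        res = prioritize.rank_cells(prob)
        union = np.zeros((5, 5), bool)
        for f in prob.features:
            union |= f.raster
        assert not (res.minimal & ~union).any()
        br = prioritize.minimal_set(res)
        assert br.range_size == res.minimal.sum()

    def test_identical_solutions_chi2_zero(self):
        cats = np.zeros((6, 6), dtype=int)
        cats[:, 3:] = 2
        zp = gap.ZoningPlan(cats)
        sol = np.zeros((6, 6), bool)
        sol[2:4, 2:4] = True
        res = prioritize.compare_solutions(sol, sol, zp)
        assert res["chi2"] == 0.0

    def test_hand_chi2(self):
        cats = np.zeros((4, 8), dtype=int)
        cats[:, 2:4] = 1
        cats[:, 4:6] = 2
        cats[:, 6:] = 3
        zp = gap.ZoningPlan(cats)
        a = np.zeros((4, 8), bool)
        a[0] = True  # 2 cells in each category
        b = np.zeros((4, 8), bool)
        b[1, :4] = True  # cats 0,0,1,1
        res = prioritize.compare_solutions(a, b, zp)
        # textbook formula on the 2x4 table [[2,2,2,2],[2,2,0,0]]
        obs = np.array([[2, 2, 2, 2], [2, 2, 0, 0]], dtype=float)
        exp = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
        expected_chi2 = ((obs - exp) ** 2 / exp).sum()
        assert np.isclose(res["chi2"], expected_chi2)
        assert res["df"] == 3

    def test_empty_solution_rejected(self):
        zp = gap.ZoningPlan(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError):
            prioritize.compare_solutions(np.zeros((3, 3), bool), np.ones((3, 3), bool), zp)
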