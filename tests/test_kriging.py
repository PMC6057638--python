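import numpy as np
import pandas as pd
import pytest

from evoreserve import kriging, synth
from evoreserve.raster import Grid
from evoreserve.sdm import BinaryRange


def make_coords(xy):
    return pd.DataFrame(xy, columns=["lon", "lat"], index=[f"s{i}" for i in range(len(xy))])


class TestEmpiricalVariogram:
    def test_all_zero_distances(self):
        coords = make_coords([(0, 0), (1, 0), (2, 0), (3, 0)])
        dist = pd.DataFrame(np.zeros((4, 4)), index=coords.index, columns=coords.index)
        emp = kriging.empirical_variogram(dist, coords, n_lags=3, cutoff=4.0)
        assert np.all(emp.semivariance[emp.pair_counts > 0] == 0.0)

    def test_collinear_hand_arithmetic(self):
        # 3 points on a line at 0, 1, 2; genetic distances set by hand
        coords = make_coords([(0, 0), (1, 0), (2, 0)])
        d01, d12, d02 = 0.6, 0.8, 1.0
        arr = np.array([[0, d01, d02], [d01, 0, d12], [d02, d12, 0.0]])
        dist = pd.DataFrame(arr, index=coords.index, columns=coords.index)
        emp = kriging.empirical_variogram(dist, coords, n_lags=2, cutoff=2.0)
        # bin 1 (geo in (0,1]): pairs (0,1),(1,2); bin 2 ((1,2]): pair (0,2)
        assert np.array_equal(emp.pair_counts, [2, 1])
        assert np.isclose(emp.semivariance[0], (d01**2 + d12**2) / (2 * 2))
        assert np.isclose(emp.semivariance[1], d02**2 / 2)

    def test_doubling_distances_quadruples_gamma(self):
        rng = np.random.default_rng(0)
        coords = make_coords(rng.random((8, 2)) * 10)
        arr = rng.random((8, 8))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 0)
        dist = pd.DataFrame(arr, index=coords.index, columns=coords.index)
        e1 = kriging.empirical_variogram(dist, coords, n_lags=4)
        e2 = kriging.empirical_variogram(dist * 2, coords, n_lags=4)
        ok = e1.pair_counts > 0
        assert np.allclose(e2.semivariance[ok], 4 * e1.semivariance[ok])

    def test_cutoff_excludes_everything(self):
        coords = make_coords([(0, 0), (10, 0), (20, 0)])
        dist = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=coords.index, columns=coords.index)
        with pytest.raises(ValueError):
            kriging.empirical_variogram(dist, coords, n_lags=3, cutoff=1.0)


class TestVariogramModel:
    def test_invariants(self):
        m = kriging.VariogramModel("spherical", nugget=0.1, sill=1.0, range_=5.0)
        h = np.linspace(0.01, 20, 200)
        g = m.gamma(h)
        assert (np.diff(g) >= -1e-12).all()
        assert np.isclose(g[-1], 1.0)
        assert np.isclose(m.gamma(np.array([1e-9]))[0], 0.1, atol=1e-6)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            kriging.VariogramModel("spherical", nugget=-0.1, sill=1.0, range_=1.0)
        with pytest.raises(ValueError):
            kriging.VariogramModel("spherical", nugget=0.5, sill=0.4, range_=1.0)
        with pytest.raises(ValueError):
            kriging.VariogramModel("bogus", 0, 1, 1)


class TestFitVariogram:
    def test_recovers_generating_model(self):
        true = kriging.VariogramModel("spherical", nugget=0.05, sill=1.0, range_=6.0)
        h = np.linspace(0.5, 12, 12)
        emp = kriging.EmpiricalVariogram(h, true.gamma(h), np.full(12, 50))
        fit = kriging.fit_variogram(emp, family="spherical")
        assert abs(fit.nugget - true.nugget) <= 0.05 * true.sill
        assert abs(fit.sill - true.sill) <= 0.05 * true.sill
        assert abs(fit.range_ - true.range_) <= 0.05 * true.range_

    def test_manual_mode_echoes(self):
        emp = kriging.EmpiricalVariogram(np.array([1.0]), np.array([0.5]), np.array([3]))
        m = kriging.fit_variogram(emp, family="gaussian", init=(0.1, 0.9, 4.0), mode="manual")
        assert (m.nugget, m.sill, m.range_) == (0.1, 0.9, 4.0)

    def test_fit_improves_on_init(self):
        true = kriging.VariogramModel("exponential", nugget=0.0, sill=2.0, range_=4.0)
        h = np.linspace(0.5, 10, 10)
        rng = np.random.default_rng(1)
        gamma = true.gamma(h) + rng.normal(0, 0.02, 10)
        emp = kriging.EmpiricalVariogram(h, gamma, np.full(10, 30))
        init = (0.5, 1.0, 1.0)
        fit = kriging.fit_variogram(emp, family="exponential", init=init)
        w = np.sqrt(emp.pair_counts)
        rss_init = np.sum(
            (w * (kriging.VariogramModel("exponential", 0.5, 1.5, 1.0).gamma(h) - gamma)) ** 2
        )
        assert fit.rss <= rss_init + 1e-9

    def test_too_few_bins(self):
        emp = kriging.EmpiricalVariogram(np.array([1.0, 2.0]), np.array([0.5, 0.6]), np.array([3, 0]))
        with pytest.raises(ValueError):
            kriging.fit_variogram(emp)


class TestKrigeIndicator:
    def test_exactness_at_samples_zero_nugget(self):
        grid = Grid(6, 6)
        vgm = kriging.VariogramModel("exponential", nugget=0.0, sill=1.0, range_=3.0)
        samples = pd.DataFrame(
            {"lon": [0.5, 3.5, 5.5], "lat": [5.5, 2.5, 0.5], "lineage": [0, 1, 1]}
        )
        probs = kriging.krige_indicator(samples, vgm, grid)
        rows, cols = grid.cell_of(samples["lon"].to_numpy(), samples["lat"].to_numpy())
        for lin in (0, 1):
            z = (samples["lineage"] == lin).astype(float).to_numpy()
            pred = probs[lin][rows, cols]
            assert np.allclose(pred, z, atol=1e-9)

    def test_all_one_lineage_constant_one(self):
        grid = Grid(5, 5)
        vgm = kriging.VariogramModel("spherical", 0.1, 1.0, 2.0)
        samples = pd.DataFrame({"lon": [1.0, 3.0], "lat": [1.0, 4.0], "lineage": [0, 0]})
        probs = kriging.krige_indicator(samples, vgm, grid)
        assert np.allclose(probs[0], 1.0)

    def test_two_sample_hand_solution(self):
        # ordinary kriging with 2 samples: closed form from the 3x3 system
        grid = Grid(1, 1, cellsize=1.0)  # single target cell centred at (0.5, 0.5)
        vgm = kriging.VariogramModel("exponential", nugget=0.0, sill=1.0, range_=2.0)
        samples = pd.DataFrame({"lon": [0.0, 2.0], "lat": [0.5, 0.5], "lineage": [0, 1]})
        # hand solution: C w + mu 1 = c0, 1'w = 1
        c12 = vgm.covariance(np.array([2.0]))[0]
        x0, y0 = 0.5, 0.5
        d1 = np.hypot(0.0 - x0, 0.5 - y0)
        d2 = np.hypot(2.0 - x0, 0.5 - y0)
        c01, c02 = vgm.covariance(np.array([d1]))[0], vgm.covariance(np.array([d2]))[0]
        # symmetric 2-sample OK weights: w1 = 1/2 + (c01-c02)/(2(1-c12))
        w1 = 0.5 + (c01 - c02) / (2 * (1 - c12))
        expected = np.clip(1.0 * w1 + 0.0 * (1 - w1), 0, 1)  # indicator of lineage 0
        probs = kriging.krige_indicator(samples, vgm, grid)
        assert np.isclose(probs[0][0, 0], expected, atol=1e-12)

    def test_probabilities_sum_to_one(self, truth):
        samples = synth.sample_occurrences(truth, 20, seed=4)
        vgm = kriging.VariogramModel("spherical", 0.1, 1.0, 10.0)
        probs = kriging.krige_indicator(samples, vgm, truth.stack.grid, truth.stack.mask)
        total = sum(probs.values())
        assert np.allclose(total[truth.stack.mask], 1.0, atol=1e-6)

    def test_duplicate_coordinates_averaged(self):
        grid = Grid(4, 4)
        vgm = kriging.VariogramModel("exponential", 0.0, 1.0, 2.0)
        samples = pd.DataFrame(
            {"lon": [1.0, 1.0, 3.0], "lat": [1.0, 1.0, 3.0], "lineage": [0, 1, 1]}
        )
        probs = kriging.krige_indicator(samples, vgm, grid)  # must not raise
        assert set(probs) == {0, 1}

    def test_domain_recovery_two_lineages(self, truth):
        # spatially segregated lineages -> kriged binaries recover the truth
        rng = np.random.default_rng(0)
        rows_list, cols_list, lin_list = [], [], []
        for lin in range(truth.n_lineages):
            rr, cc = np.nonzero(truth.domains == lin)
            take = rng.choice(len(rr), size=12, replace=False)
            rows_list.append(rr[take])
            cols_list.append(cc[take])
            lin_list.append(np.full(12, lin))
        rows = np.concatenate(rows_list)
        cols = np.concatenate(cols_list)
        lon, lat = truth.stack.grid.cell_center(rows, cols)
        samples = pd.DataFrame({"lon": lon, "lat": lat, "lineage": np.concatenate(lin_list)})
        vgm = kriging.VariogramModel("spherical", nugget=0.02, sill=1.0, range_=15.0)
        probs = kriging.krige_indicator(samples, vgm, truth.stack.grid, truth.stack.mask)
        pred = np.argmax(np.stack([probs[0], probs[1]]), axis=0)
        in_range = truth.range_mask
        agree = (pred[in_range] == truth.domains[in_range]).mean()
        assert agree >= 0.9


class TestLineageBinary:
    def _species(self):
        raster = np.zeros((4, 4), bool)
        raster[:2] = True
        return BinaryRange("sp", "species", raster)

    def test_prob_one_equals_species_range(self):
        sp = self._species()
        out = kriging.lineage_binary(np.ones((4, 4)), sp, "sp_0")
        assert np.array_equal(out.raster, sp.raster)

    def test_prob_below_half_empty(self):
        sp = self._species()
        out = kriging.lineage_binary(np.full((4, 4), 0.49), sp, "sp_0")
        assert out.range_size == 0

    def test_empty_species_range_empty(self):
        sp = BinaryRange("sp", "species", np.zeros((4, 4), bool))
        out = kriging.lineage_binary(np.ones((4, 4)), sp, "sp_0")
        assert out.range_size == 0

    def test_grid_mismatch(self):
        sp = self._species()
        with pytest.raises(ValueError):
            kriging.lineage_binary(np.ones((5, 5)), sp, "sp_0")
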