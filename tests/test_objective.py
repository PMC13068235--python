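import numpy as np
import pytest

import pgfinfer as pg
from pgfinfer.families import TelegraphFamily
from pgfinfer.objective import _cached_epgf

from conftest import TELEGRAPH_THETA, inject_exact_epgf


class TestEmpiricalPGF:
    def test_three_cell_example(self):
        vals = pg.empirical_pgf(np.array([0, 1, 2]), np.array([0.5]))
        assert vals[0] == pytest.approx((1 + 0.5 + 0.25) / 3, rel=1e-14)

    def test_normalized_at_one(self, steady_counts):
        assert pg.empirical_pgf(steady_counts, np.array([1.0]))[0] == pytest.approx(1.0)

    def test_two_species_example(self):
        counts = np.array([[1, 0], [0, 2]])
        vals = pg.empirical_pgf(counts, np.array([[0.5, 0.5]]))
        assert vals[0] == pytest.approx(0.375, rel=1e-14)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            pg.empirical_pgf(np.empty((0, 1), dtype=int), np.array([0.5]))

    def test_pooled_batches_are_count_weighted_means(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(4, size=300)
        b = rng.poisson(4, size=700)
        z = np.linspace(0, 1, 5)
        pooled = pg.empirical_pgf(np.concatenate([a, b]), z)
        weighted = 0.3 * pg.empirical_pgf(a, z) + 0.7 * pg.empirical_pgf(b, z)
        assert np.allclose(pooled, weighted, rtol=1e-12)


class TestGaussGrid:
    def test_two_point_rule_on_unit_interval(self):
        g = pg.gauss_grid(2, 0.0, 1.0)
        assert np.allclose(sorted(g.nodes[:, 0]), [0.5 - 0.5 / np.sqrt(3), 0.5 + 0.5 / np.sqrt(3)])
        assert np.allclose(g.weights, [1.0, 1.0])
        assert g.a_z == 0.5

    def test_exact_for_cubics(self):
        g = pg.gauss_grid(2, 0.0, 1.0)
        assert g.integrate(g.nodes[:, 0] ** 2) == pytest.approx(1 / 3, rel=1e-14)
        assert g.integrate(g.nodes[:, 0] ** 3) == pytest.approx(1 / 4, rel=1e-14)

    def test_affine_constants_for_tail_range(self):
        g = pg.gauss_grid(8, 0.9, 1.0)
        assert g.a_z == pytest.approx(0.05)
        assert g.b_z == pytest.approx(0.95)
        assert np.all((g.nodes >= 0.9) & (g.nodes <= 1.0))

    @pytest.mark.parametrize("ndim", [1, 2, 3])
    def test_constant_integrates_to_box_volume(self, ndim):
        g = pg.gauss_grid(4, 0.2, 0.8, ndim=ndim)
        vol = 0.6 ** ndim
        assert g.integrate(np.ones(g.nodes.shape[0])) == pytest.approx(vol, rel=1e-13)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pg.gauss_grid(0)
        with pytest.raises(ValueError):
            pg.gauss_grid(4, 1.0, 0.0)
        with pytest.raises(ValueError):
            pg.gauss_grid(4, 0, 1, ndim=4)


class TestSteadyLoss:
    def test_zero_at_exact_match_fixed_point(self, steady_counts):
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        theta = np.array([10.0, 1.0, 1.0, 1.0])
        inject_exact_epgf(steady_counts, grid, fam, theta)
        try:
            assert pg.loss_steady(theta, fam, steady_counts, grid) < 1e-28
        finally:
            steady_counts._epgf_cache = {}

    def test_nonnegative(self, steady_counts):
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        for theta in ([1, 1, 1, 1], [30, 3, 10, 1], [5, 0.1, 0.1, 1]):
            assert pg.loss_steady(np.array(theta, float), fam, steady_counts, grid) >= 0

    def test_true_parameters_beat_scaled_parameters(self, telegraph_model):
        data = pg.simulate_snapshots(pg.SimProtocol(telegraph_model, n_c=10000, seed=21))
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        theta = np.append(TELEGRAPH_THETA, 1.0)
        scaled = np.append(3 * TELEGRAPH_THETA, 1.0)  # d stays the unit
        assert pg.loss_steady(theta, fam, data, grid) < pg.loss_steady(scaled, fam, data, grid)

    def test_quadrature_converged_at_default_order(self, steady_counts):
        fam = TelegraphFamily()
        theta = np.array([10.0, 1.0, 1.0, 1.0])
        j8 = pg.loss_steady(theta, fam, steady_counts, pg.gauss_grid(8))
        j16 = pg.loss_steady(theta, fam, steady_counts, pg.gauss_grid(16))
        assert abs(j8 - j16) < 1e-10

    def test_epgf_cached_across_theta_evaluations(self, telegraph_model):
        data = pg.simulate_snapshots(pg.SimProtocol(telegraph_model, n_c=500, seed=3))
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        pg.loss_steady(np.array([10.0, 1, 1, 1]), fam, data, grid)
        cached = _cached_epgf(data, grid, 0)
        pg.loss_steady(np.array([2.0, 1, 1, 1]), fam, data, grid)
        assert _cached_epgf(data, grid, 0) is cached


class TestTimeLoss:
    def test_single_snapshot_equals_steady_loss(self, telegraph_model):
        data = pg.simulate_snapshots(
            pg.SimProtocol(telegraph_model, n_c=800, times=(6.0,), seed=9)
        )
        steady_version = pg.CountDataset(data.at(0))
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        theta = np.array([10.0, 1.0, 1.0, 1.0])
        jt = pg.loss_time(theta, fam, data, grid)
        # at t=6 the transient PGF has relaxed to the steady solution
        js = pg.loss_steady(theta, fam, steady_version, grid)
        assert jt == pytest.approx(js, abs=1e-8)

    def test_zero_at_exact_match_fixed_point(self, time_counts):
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        theta = np.array([10.0, 1.0, 1.0, 1.0])
        inject_exact_epgf(time_counts, grid, fam, theta, times=time_counts.times)
        try:
            assert pg.loss_time(theta, fam, time_counts, grid) < 1e-24
        finally:
            time_counts._epgf_cache = {}

    def test_replacing_a_snapshot_by_the_model_pgf_cannot_increase_loss(self, time_counts):
        fam = TelegraphFamily()
        grid = pg.gauss_grid(8)
        theta = np.array([10.0, 1.0, 1.0, 1.0])
        j_full = pg.loss_time(theta, fam, time_counts, grid)
        # overwrite the last snapshot's EPGF with the exact model values
        z = grid.nodes[:, 0]
        vals = fam.time_pgf(theta, z, time_counts.times)
        from pgfinfer.objective import _cached_epgf as ce

        for j in range(time_counts.n_times):
            ce(time_counts, grid, j)
        key = grid.key() + (time_counts.n_times - 1,)
        old = time_counts._epgf_cache[key]
        time_counts._epgf_cache[key] = vals[-1]
        try:
            assert pg.loss_time(theta, fam, time_counts, grid) <= j_full
        finally:
            time_counts._epgf_cache[key] = old

    def test_steady_data_rejected(self, steady_counts):
        with pytest.raises(ValueError):
            pg.loss_time(np.array([10.0, 1, 1, 1]), TelegraphFamily(), steady_counts, pg.gauss_grid(8))
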