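import numpy as np
import pytest

import pgfinfer as pg


class TestBuildFsp:
    def test_hand_constructed_telegraph_blocks(self):
        m = pg.make_telegraph(1, 1, 1, 1)
        A = pg.build_fsp(m, 1).A.toarray()
        A1 = A[:2, :2]  # inactive block
        A2 = A[:2, 2:]  # active -> inactive switching
        A3 = A[2:, :2]
        A4 = A[2:, 2:]
        assert np.array_equal(A1, [[-1, 1], [0, -2]])
        assert np.array_equal(A2, np.eye(2))
        assert np.array_equal(A3, np.eye(2))
        assert np.array_equal(A4, [[-2, 1], [1, -3]])

    def test_column_sums_leak_only_at_transcribing_boundary(self):
        m = pg.make_telegraph(7, 1, 2, 1)
        system = pg.build_fsp(m, 10)
        sums = np.asarray(system.A.sum(axis=0)).ravel()
        # inactive block columns and interior active columns balance
        assert np.allclose(sums[:11], 0, atol=1e-12)
        assert np.allclose(sums[11:-1], 0, atol=1e-12)
        assert sums[-1] == pytest.approx(-7.0)  # boundary leak = -rho

    def test_closed_system_without_transcription(self):
        m = pg.GeneStateModel(Q=np.array([[-1.0, 1.0], [1.0, -1.0]]), rho=np.zeros(2), d=1.0)
        system = pg.build_fsp(m, 5)
        assert np.allclose(np.asarray(system.A.sum(axis=0)).ravel(), 0, atol=1e-12)


class TestSteadySolve:
    def test_normalized_by_construction(self, telegraph_model):
        p = pg.fsp_steady(pg.build_fsp(telegraph_model, 60))
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(p >= 0)

    def test_matches_pgf_inversion(self, telegraph_model):
        system = pg.build_fsp(telegraph_model, 60)
        fsp_pmf = system.marginal_mrna(pg.fsp_steady(system))
        G = pg.PGFunction(lambda z: pg.telegraph_pgf_steady((10, 1, 1), z))
        assert 0.5 * np.abs(fsp_pmf - pg.pgf_to_pmf(G, 60)).sum() < 1e-6

    def test_birth_death_limit_is_poisson(self):
        m = pg.make_telegraph(5, 1, 0, 1)
        system = pg.build_fsp(m, 60)
        pmf = system.marginal_mrna(pg.fsp_steady(system))
        assert pmf[0] == pytest.approx(np.exp(-5), rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_theta_oracle_agreement(self, seed):
        theta = pg.sample_parameters(n_sets=1, seed=seed)[0].values
        m = pg.make_telegraph(*theta)
        n_T = pg.choose_truncation(model=m)
        system = pg.build_fsp(m, n_T)
        fsp_pmf = system.marginal_mrna(pg.fsp_steady(system))
        G = pg.PGFunction(lambda z: pg.telegraph_pgf_steady(tuple(theta[:3]), z))
        assert 0.5 * np.abs(fsp_pmf - pg.pgf_to_pmf(G, n_T)).sum() < 1e-6


class TestTransientSolve:
    def test_initial_condition(self, telegraph_model):
        system = pg.build_fsp(telegraph_model, 40)
        p = pg.fsp_time(system, [0.0])[0]
        assert p[system.model.init_state * 41] == 1.0
        assert p.sum() == 1.0

    def test_mass_loss_monotone(self, telegraph_model):
        system = pg.build_fsp(telegraph_model, 60)
        sols = pg.fsp_time(system, [0.5, 2.0, 6.0])
        losses = 1.0 - sols.sum(axis=1)
        assert np.all(np.diff(losses) >= -1e-12)

    def test_relaxes_to_steady_state(self, telegraph_model):
        system = pg.build_fsp(telegraph_model, 60)
        p20 = pg.fsp_time(system, [20.0])[0]
        ps = pg.fsp_steady(system)
        assert np.max(np.abs(p20 - ps)) < 1e-6

    def test_undersized_truncation_raises(self, telegraph_model):
        system = pg.build_fsp(telegraph_model, 3)
        with pytest.raises(RuntimeError):
            pg.fsp_time(system, [6.0])


class TestTruncationChoice:
    def test_at_least_the_observed_maximum(self):
        ds = pg.CountDataset(np.array([0, 3, 42])[:, None])
        assert pg.choose_truncation(data=ds) >= 42

    def test_poisson_limit_formula(self):
        m = pg.make_telegraph(5, 1, 1e-9, 1)
        assert pg.choose_truncation(model=m) >= 5 + 10 * np.sqrt(5) - 1

    def test_escalation_terminates_inside_likelihood(self, telegraph_model):
        ds = pg.simulate_snapshots(pg.SimProtocol(telegraph_model, n_c=200, seed=13))
        model = pg.FspMaximumLikelihood(ds)
        model.loss(np.array([10.0, 1.0, 1.0, 1.0]))  # escalates as needed
        system = pg.build_fsp(telegraph_model, model.n_T)
        pmf = system.marginal_mrna(pg.fsp_steady(system))
        assert pmf[-1] < 1e-10


class TestLikelihood:
    def test_two_zero_cells_toy_value(self):
        # s_off = 0 gives Poisson(rho/d); rho = ln 4 puts P(0) = 0.25
        ds = pg.CountDataset(np.array([0, 0])[:, None])
        model = pg.FspMaximumLikelihood(ds)
        nll = model.nll(np.array([np.log(4.0), 1.0, 1e-12, 1.0]))
        assert nll == pytest.approx(-2 * np.log(0.25), rel=1e-8)

    def test_minimized_at_truth_on_exact_distribution(self, telegraph_model):
        """Feeding the exact FSP PMF as (fractional) count weights makes
        the NLL a cross-entropy minimized at the generating parameters."""
        n_T = 70
        system = pg.build_fsp(telegraph_model, n_T)
        pmf = system.marginal_mrna(pg.fsp_steady(system))
        ds = pg.CountDataset(np.array([0, 1])[:, None])  # placeholder
        model = pg.FspMaximumLikelihood(ds, n_T=n_T)
        model.histograms = [(np.arange(n_T + 1), pmf * 1000.0)]
        res = model.fit(start=np.log(np.array([12.0, 1.3, 0.8])))
        assert np.max(np.abs(res.params.values[:3] - [10, 1, 1]) / np.array([10, 1, 1])) < 1e-2

    def test_ssa_recovery_is_reasonable(self, steady_counts):
        res = pg.mle_infer(steady_counts)
        assert res.relative_error(np.array([10.0, 1.0, 1.0])) < 0.5
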