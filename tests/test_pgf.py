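import numpy as np
import pytest

import pgfinfer as pg
from pgfinfer.pgf import poisson_pgf


class TestTelegraphSteadyPGF:
    def test_poisson_special_case_at_zero(self):
        # s_off = 0 makes the active state permanent: Poisson(rho),
        # and M(a, a, x) = e^x
        assert pg.telegraph_pgf_steady((2, 1, 0), 0.0) == pytest.approx(np.exp(-2), rel=1e-12)

    @pytest.mark.parametrize("theta", [(10, 1, 1), (30, 0.01, 10), (1, 3, 0.01)])
    def test_normalized_at_one(self, theta):
        assert pg.telegraph_pgf_steady(theta, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_m_1_2(self):
        # M(1, 2, x) = (e^x - 1)/x; theta=(10,1,1) at z=0.9 gives x=-1
        val = pg.telegraph_pgf_steady((10, 1, 1), 0.9)
        assert val == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_poisson_limit_on_grid(self):
        z = np.linspace(0, 1, 50)
        rho = 7.3
        vals = pg.telegraph_pgf_steady((rho, 2.0, 0.0), z)
        assert np.max(np.abs(vals - np.exp(rho * (z - 1)))) < 1e-8

    def test_monotone_nondecreasing_on_unit_interval(self):
        z = np.linspace(0, 1, 101)
        vals = pg.telegraph_pgf_steady((25, 0.3, 4.0), z)
        assert np.all(np.diff(vals) >= -1e-14)

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            pg.telegraph_pgf_steady((-1, 1, 1), 0.5)


class TestTimePGF:
    def test_degenerate_initial_distribution(self, telegraph_model):
        for z in (0.0, 0.4, 1.0):
            assert pg.model_pgf_time(telegraph_model, z, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_no_transcription_means_unit_pgf(self):
        m = pg.GeneStateModel(
            Q=np.array([[-1.0, 1.0], [1.0, -1.0]]), rho=np.zeros(2), d=1.0
        )
        vals = pg.pgf_time_grid(m, np.array([0.0, 0.5, 1.0]), [1.0, 5.0])
        assert np.allclose(vals, 1.0, atol=1e-10)

    def test_relaxation_to_steady_state(self, telegraph_model):
        at_20 = pg.model_pgf_time(telegraph_model, 0.5, 20.0)
        assert at_20 == pytest.approx(pg.telegraph_pgf_steady((10, 1, 1), 0.5), abs=1e-6)

    def test_steady_dispatch_matches_kummer(self, telegraph_model):
        z = np.linspace(0, 1, 7)
        assert np.allclose(
            pg.model_pgf_steady(telegraph_model, z),
            pg.telegraph_pgf_steady((10, 1, 1), z),
            rtol=1e-12,
        )

    def test_refractory_steady_mean_from_occupancy(self, refractory_model):
        # mean = rho * pi_active / d = 20/3 for the symmetric cycle
        G = pg.PGFunction(lambda z: pg.model_pgf_steady(refractory_model, z))
        mean, _, _ = pg.pgf_moments(G)
        assert mean == pytest.approx(20 / 3, rel=1e-6)

    def test_refractory_steady_normalized(self, refractory_model):
        assert pg.model_pgf_steady(refractory_model, 1.0) == pytest.approx(1.0, abs=1e-8)


class TestPGFAlgebra:
    def test_thinned_poisson_is_poisson(self):
        G = pg.thin_pgf(poisson_pgf(4.0), 0.5)
        z = np.linspace(0, 1, 9)
        assert np.allclose(G(z), poisson_pgf(2.0)(z), rtol=1e-12)

    def test_full_capture_is_identity(self):
        G = pg.thin_pgf(poisson_pgf(3.0), 1.0)
        z = np.linspace(0, 1, 5)
        assert np.allclose(G(z), poisson_pgf(3.0)(z))

    def test_complete_zero_inflation(self):
        G = pg.zero_inflate_pgf(poisson_pgf(2.0), 1.0)
        assert np.allclose(G(np.linspace(0, 1, 5)), 1.0)

    def test_product_of_independent_poissons(self):
        G = pg.product_pgf(poisson_pgf(1.0), poisson_pgf(2.0))
        z = np.linspace(0, 1, 9)
        assert np.allclose(G(z), poisson_pgf(3.0)(z), rtol=1e-12)

    def test_marginal_of_joint_is_normalized(self):
        joint = pg.PGFunction(
            lambda zs: np.exp(1.0 * (np.asarray(zs[0]) - 1)) * np.exp(2.0 * (np.asarray(zs[1]) - 1)),
            ndim=2,
        )
        marg = pg.marginalize(joint, [0])
        assert marg(1.0) == pytest.approx(1.0, abs=1e-14)
        assert marg(0.5) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            pg.thin_pgf(poisson_pgf(1.0), 1.5)
        with pytest.raises(ValueError):
            pg.zero_inflate_pgf(poisson_pgf(1.0), -0.1)

    def test_thinned_telegraph_pmf_is_binomial_mixture_of_fsp(self, telegraph_model):
        """Thinning in PGF space must equal explicit binomial thinning of
        the FSP steady-state PMF."""
        p = 0.5
        n_T = 70
        system = pg.build_fsp(telegraph_model, n_T)
        pmf = system.marginal_mrna(pg.fsp_steady(system))
        n = np.arange(n_T + 1)
        from scipy.stats import binom

        thinned_explicit = np.zeros(n_T + 1)
        for k, pk in enumerate(pmf):
            thinned_explicit[: k + 1] += pk * binom.pmf(n[: k + 1], k, p)
        G = pg.thin_pgf(
            pg.PGFunction(lambda z: pg.telegraph_pgf_steady((10, 1, 1), z)), p
        )
        thinned_pgf = pg.pgf_to_pmf(G, n_T)
        assert 0.5 * np.abs(thinned_pgf - thinned_explicit).sum() < 1e-6


class TestInversionAndMoments:
    def test_poisson_head_probability(self):
        pmf = pg.pgf_to_pmf(poisson_pgf(2.0), 20)
        assert pmf[0] == pytest.approx(np.exp(-2), rel=1e-10)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-8)

    def test_mass_recovered_as_truncation_grows(self):
        G = poisson_pgf(8.0)
        masses = [pg.pgf_to_pmf(G, n).sum() for n in (8, 16, 40)]
        assert masses == sorted(masses)
        assert masses[-1] == pytest.approx(1.0, abs=1e-8)

    def test_warns_when_truncation_loses_mass(self):
        with pytest.warns(RuntimeWarning):
            pg.pgf_to_pmf(poisson_pgf(30.0), 10)

    def test_telegraph_closed_form_moments(self):
        G = pg.PGFunction(lambda z: pg.telegraph_pgf_steady((10, 1, 1), z))
        mean, var, mu3 = pg.pgf_moments(G)
        assert mean == pytest.approx(5.0, rel=1e-6)
        assert var == pytest.approx(5 + 100 / 12, rel=1e-6)
        assert mu3 == pytest.approx(30.0, rel=1e-6)


def test_transient_pgf_matches_fsp_oracle(telegraph_model, refractory_model):
    """The characteristics solution and the FSP-summed PGF are two
    independent routes to G(z, t); they must agree everywhere."""
    z = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    times = [0.5, 2.0, 6.0]
    for model, n_T in ((telegraph_model, 60), (refractory_model, 80)):
        system = pg.build_fsp(model, n_T)
        sols = pg.fsp_time(system, times)
        Gt = pg.pgf_time_grid(model, z, times)
        n = np.arange(n_T + 1)
        for j in range(len(times)):
            marg = system.marginal_mrna(sols[j])
            fsp_vals = np.array([(marg * zi ** n).sum() for zi in z])
            assert np.max(np.abs(fsp_vals - Gt[j])) < 1e-6
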