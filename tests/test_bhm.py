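"""Adjacency construction, likelihoods, MCMC sanity and exceedance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

import maskgap as mg
from conftest import make_intercept_only_frame


def frame_of(geoms):
    return pd.DataFrame(
        {"village_id": [f"V{i}" for i in range(len(geoms))], "geometry": geoms}
    )


class TestAdjacency:
    def test_2x2_grid_queen(self):
        geoms = [box(x, y, x + 1, y + 1) for y in range(2) for x in range(2)]
        adj = mg.build_adjacency(frame_of(geoms))
        assert (adj.N == 3).all()  # every cell touches the other three
        assert (adj.a == adj.a.T).all()
        assert np.trace(adj.a) == 0

    def test_1x3_strip(self):
        geoms = [box(x, 0, x + 1, 1) for x in range(3)]
        adj = mg.build_adjacency(frame_of(geoms))
        assert list(adj.N) == [1, 2, 1]

    def test_island_component(self):
        geoms = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(5, 5, 6, 6)]
        adj = mg.build_adjacency(frame_of(geoms))
        assert adj.N[2] == 0
        assert adj.n_components == 2

    def test_matches_brute_force_on_random_tessellation(self, small_villages):
        vil, _ = small_villages
        adj = mg.build_adjacency(vil)
        geoms = list(vil["geometry"])
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                touch = geoms[i].intersects(geoms[j])
                assert bool(adj.a[i, j]) == touch


class TestLogLikelihood:
    def test_poisson_closed_form(self):
        ll = mg.log_likelihood(
            np.array([0]), np.array([1.0]), {"lam": np.array([1.0])}, "poisson"
        )
        assert ll[0] == pytest.approx(-1.0)

    def test_negbin_poisson_limit(self):
        Y = np.arange(0, 30)
        lam = np.full(30, 7.3)
        E = np.ones(30)
        ll_nb = mg.log_likelihood(Y, E, {"lam": lam, "theta": 1e8}, "negbin")
        ll_p = mg.log_likelihood(Y, E, {"lam": lam}, "poisson")
        assert np.max(np.abs(ll_nb - ll_p)) < 1e-4

    def test_negbin_variance_parameterization(self):
        # mean lam, variance lam + lam^2/theta: at lam=10, theta=1.6 -> 72.5
        lam, theta = 10.0, 1.6
        dist = stats.nbinom(theta, theta / (theta + lam))
        assert dist.mean() == pytest.approx(lam)
        assert dist.var() == pytest.approx(lam + lam**2 / theta)
        assert dist.var() == pytest.approx(72.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mg.log_likelihood(
                np.array([-1]), np.array([1.0]), {"lam": np.array([1.0])}, "poisson"
            )


class TestModelSpec:
    def test_iterations_must_exceed_burnin(self):
        with pytest.raises(ValueError):
            mg.ModelSpec(iterations=100, burnin=100)

    def test_two_chains_minimum(self):
        with pytest.raises(ValueError):
            mg.ModelSpec(chains=1)


class TestFit:
    def test_intercept_only_identity_data(self):
        """Y_i = E_i for all i: posterior mean of the intercept is ~0."""
        vil = make_intercept_only_frame(200)
        adj = mg.Adjacency(
            a=np.zeros((200, 200), dtype=np.int8),
            N=np.zeros(200, dtype=np.int64),
            components=np.arange(200),
        )
        spec = mg.ModelSpec(
            family="poisson", chains=2, iterations=1500, burnin=750, thin=2, seed=1
        )
        fit = mg.fit(spec, vil, adj)
        b0 = fit.summary.set_index("parameter").loc["intercept", "mean"]
        assert abs(b0) < 0.05

    def test_aspatial_posterior_matches_glm_oracle(self, small_villages):
        """With vague priors the aspatial Poisson posterior sits on the MLE."""
        import statsmodels.api as sm

        vil, _ = small_villages
        adj = mg.build_adjacency(vil)
        spec = mg.ModelSpec(
            family="poisson", chains=2, iterations=2000, burnin=1000, thin=2, seed=2
        )
        fit = mg.fit(spec, vil, adj)
        X = mg.design_matrix(vil)
        glm = sm.GLM(
            vil["Y"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.log(vil["E"].to_numpy()),
        ).fit()
        post = fit.summary.set_index("parameter")
        for j, name in enumerate(mg.bhm.DESIGN_NAMES):
            mean, sd = post.loc[name, "mean"], post.loc[name, "sd"]
            assert abs(mean - glm.params[j]) < 4 * glm.bse[j]
            assert 0.5 < sd / glm.bse[j] < 2.0

    def test_posterior_quantiles_ordered(self, fitted_spatial):
        fit, _, _ = fitted_spatial
        s = fit.summary
        assert (s["q025"] <= s["q50"]).all() and (s["q50"] <= s["q975"]).all()

    def test_lambda_equals_E_times_rho(self, fitted_spatial):
        fit, vil, _ = fitted_spatial
        rho = fit.rho_draws()
        lam = fit.E[None, :] * rho
        assert np.all(lam > 0)
        assert lam.shape == (fit.n_draws, fit.modeled.sum())

    def test_zero_population_villages_excluded(self, small_villages):
        vil, _ = small_villages
        vil2 = vil.copy()
        vil2.loc[vil2.index[:3], "E"] = 0.0
        adj = mg.build_adjacency(vil2)
        spec = mg.ModelSpec(
            family="poisson", chains=2, iterations=600, burnin=300, seed=3
        )
        fit = mg.fit(spec, vil2, adj)
        assert fit.modeled.sum() == len(vil2) - 3


class TestExceedance:
    def test_all_below_threshold(self):
        draws = np.full((100, 4), 0.5)
        assert (mg.bhm.exceedance_from_draws(draws, 1.0) == 1.0).all()

    def test_symmetric_draws_half(self):
        draws = np.concatenate([np.full((500, 1), 0.5), np.full((500, 1), 1.5)])
        assert mg.bhm.exceedance_from_draws(draws, 1.0)[0] == pytest.approx(0.5)

    def test_lognormal_oracle(self):
        rng = np.random.default_rng(4)
        draws = np.exp(rng.standard_normal((20000, 1)))
        p = mg.bhm.exceedance_from_draws(draws, 1.0)[0]
        assert p == pytest.approx(stats.norm.cdf(0.0), abs=0.02)

    def test_monotone_in_threshold(self, fitted_spatial):
        fit, _, _ = fitted_spatial
        ps = [mg.exceedance(fit, t).mean() for t in (0.5, 1.0, 2.0)]
        assert ps[0] <= ps[1] <= ps[2]
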