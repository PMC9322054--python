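"""Likelihood pieces, iCAR prior, sampler behaviour and effect transforms."""

import math

import numpy as np
import pandas as pd
import pytest

from arealrisk.bym import (BYMModel, ModelData, ModelSpec,
                           icar_logpdf_and_conditionals, linear_predictor,
                           nb_log_likelihood, percent_change, rr_per_unit)
from arealrisk.simulate import SimulationConfig, simulate_study
from .conftest import grid_lattice


def nb_logpmf_oracle(y, mu, alpha):
    """Independent NB2 log-pmf via lgamma, one observation at a time."""
    return (math.lgamma(y + alpha) - math.lgamma(alpha) - math.lgamma(y + 1)
            + alpha * math.log(alpha / (alpha + mu))
            + y * math.log(mu / (alpha + mu)))


class TestNBLikelihood:
    def test_single_observation_matches_gamma_oracle(self):
        got = nb_log_likelihood([3], [2.0], 5.0)
        assert got == pytest.approx(nb_logpmf_oracle(3, 2.0, 5.0), abs=1e-9)

    def test_vector_matches_oracle(self, rng):
        y = rng.poisson(10, size=40)
        mu = rng.uniform(1, 30, size=40)
        alpha = 2.7
        oracle = sum(nb_logpmf_oracle(int(yi), float(mi), alpha)
                     for yi, mi in zip(y, mu))
        assert nb_log_likelihood(y, mu, alpha) == pytest.approx(oracle, abs=1e-9)

    def test_poisson_limit(self, rng):
        from scipy.stats import poisson
        mu = rng.uniform(2, 20, size=50)
        y = rng.poisson(mu)
        nb = nb_log_likelihood(y, mu, 1e8)
        pois = float(poisson.logpmf(y, mu).sum())
        assert nb == pytest.approx(pois, abs=1e-5)

    def test_nb_sampler_moments(self):
        # Gamma-Poisson mixture must hit Var = mu + mu^2/alpha
        rng = np.random.default_rng(7)
        mu, alpha, n = 10.0, 2.0, 200_000
        lam = rng.gamma(alpha, mu / alpha, size=n)
        y = rng.poisson(lam)
        assert y.mean() == pytest.approx(mu, rel=0.02)
        assert y.var() == pytest.approx(mu + mu ** 2 / alpha, rel=0.05)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            nb_log_likelihood([1.5], [2.0], 1.0)
        with pytest.raises(ValueError):
            nb_log_likelihood([-1], [2.0], 1.0)
        with pytest.raises(ValueError):
            nb_log_likelihood([1], [2.0], -1.0)


class TestLinearPredictor:
    def test_all_zero_with_unit_population(self):
        eta = linear_predictor(0.0, [], np.empty((3, 0)), np.log(np.ones(3)))
        assert np.allclose(np.exp(eta), 1.0)

    def test_offset_contract_population_doubles_mu(self, rng):
        X = rng.standard_normal((5, 2))
        pop = rng.uniform(1e3, 1e5, size=5)
        e1 = linear_predictor(-5.0, [0.3, -0.2], X, np.log(pop))
        e2 = linear_predictor(-5.0, [0.3, -0.2], X, np.log(2 * pop))
        assert np.allclose(np.exp(e2), 2 * np.exp(e1))

    def test_matches_per_area_loop_oracle(self, rng):
        n, p = 8, 3
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        b0 = rng.standard_normal()
        pop = rng.uniform(10, 100, size=n)
        u, v = rng.standard_normal(n), rng.standard_normal(n)
        eta = linear_predictor(b0, beta, X, np.log(pop), u, v)
        for i in range(n):
            manual = b0 + sum(X[i, k] * beta[k] for k in range(p)) \
                + math.log(pop[i]) + u[i] + v[i]
            assert eta[i] == pytest.approx(manual, abs=1e-12)


class TestICAR:
    def test_constant_within_component_maximal(self, path3):
        d = icar_logpdf_and_conditionals(np.zeros(3), path3, 1.0)
        d2 = icar_logpdf_and_conditionals(np.array([-1.0, 0.0, 1.0]), path3, 1.0)
        assert d.logpdf > d2.logpdf

    def test_path_conditional_mean_and_variance(self, path3):
        d = icar_logpdf_and_conditionals(np.array([-1.0, 0.0, 1.0]), path3, 0.5)
        b = path3.index_of("B")
        assert d.cond_mean[b] == pytest.approx(0.0)
        assert d.cond_var[b] == pytest.approx(0.5 / 2)

    def test_pairwise_form_equals_dense_quadratic_oracle(self, rng):
        lat = grid_lattice(6, 5, diagonal=True)
        u = rng.standard_normal(lat.n_areas)
        u -= u.mean()
        sigma2 = 0.7
        d = icar_logpdf_and_conditionals(u, lat, sigma2)
        W = lat.adjacency_matrix().toarray()
        L = np.diag(W.sum(axis=1)) - W
        quad = float(u @ L @ u)
        n_struct = lat.n_areas
        expected = -0.5 * quad / sigma2 - 0.5 * (n_struct - 1) * np.log(sigma2)
        assert d.logpdf == pytest.approx(expected, abs=1e-9)


class TestTransforms:
    @pytest.mark.parametrize("coef,delta,expected,digits", [
        (-0.492, 0.1, 0.952, 3),   # protective green-space RR per +10 points
        (0.0, 0.37, 1.0, 6),
        (0.562, 1.0, 1.75, 2),     # per-degree minimum-temperature RR
    ])
    def test_rr(self, coef, delta, expected, digits):
        assert round(rr_per_unit(coef, delta), digits) == expected

    @pytest.mark.parametrize("coef,delta,expected,digits", [
        (-0.492, 0.1, 4.8, 1),
        (-0.592, 0.1, 5.75, 2),
        (0.0, 1.0, 0.0, 6),
    ])
    def test_percent_change(self, coef, delta, expected, digits):
        assert round(percent_change(coef, delta), digits) == expected


def small_dataset(seed=5, rows=7, cols=7, **kw):
    cfg = SimulationConfig(rows=rows, cols=cols, n_islands=0,
                           covariates=("green_space", "populous_grassroots"),
                           seed=seed, **kw)
    return simulate_study(cfg)


FAST = dict(n_chains=2, n_iter=1200, burn_in=500, thin=2)


class TestFit:
    def test_intercept_only_poisson_matches_crude_rate(self):
        st = small_dataset(seed=11, beta={}, sigma_u2=0.0, sigma_v2=0.0,
                           alpha=1e13)
        d = st["data"]
        res = BYMModel(d, covariates=(), likelihood="poisson",
                       include_random_effects=False, **FAST, seed=2).fit()
        crude = d.y.sum() / d.population.sum()
        b0 = res.summary_frame.loc["intercept", "mean"]
        sd = res.summary_frame.loc["intercept", "sd"]
        assert abs(np.exp(b0) - crude) / crude < 0.02
        assert abs(b0 - np.log(crude)) < 4 * sd

    def test_chain_determinism_bitwise(self):
        st = small_dataset(seed=3)
        r1 = BYMModel(st["data"], **FAST, seed=99).fit()
        r2 = BYMModel(st["data"], **FAST, seed=99).fit()
        pd.testing.assert_frame_equal(r1.summary_frame, r2.summary_frame)
        assert np.array_equal(r1.draws["u"], r2.draws["u"])

    def test_sum_to_zero_every_retained_draw(self):
        st = small_dataset(seed=4)
        res = BYMModel(st["data"], **FAST, seed=1).fit()
        sums = res.draws["u"].sum(axis=2)
        assert np.abs(sums).max() < 1e-9

    def test_dic_identities_and_positive_pd(self):
        st = small_dataset(seed=6)
        res = BYMModel(st["data"], **FAST, seed=1).fit()
        c = res.dic_components
        assert c["DIC"] == pytest.approx(c["Dbar"] + c["pD"], abs=1e-9)
        assert c["pD"] == pytest.approx(c["Dbar"] - c["D_hat"], abs=1e-9)
        assert c["pD"] > 0

    def test_quantile_bounds_ordered_and_significance_flags(self):
        st = small_dataset(seed=8)
        res = BYMModel(st["data"], **FAST, seed=5).fit()
        s = res.summary_frame
        assert (s["2.5%"] <= s["50%"]).all() and (s["50%"] <= s["97.5%"]).all()
        for name in res.coef_names:
            row = s.loc[name]
            assert res.significant(name) == bool(row["2.5%"] > 0 or row["97.5%"] < 0)

    def test_residual_rr_and_spatial_sd_against_draw_oracle(self):
        st = small_dataset(seed=9)
        res = BYMModel(st["data"], **FAST, seed=5).fit()
        u = res.draws["u"].reshape(-1, st["data"].lattice.n_areas)
        v = res.draws["v"].reshape(-1, st["data"].lattice.n_areas)
        # two-pass oracle over stored draws
        rr_oracle = np.exp(u + v).mean(axis=0)
        eff = u + v
        sd_oracle = np.sqrt(((eff - eff.mean(axis=0)) ** 2).sum(axis=0)
                            / (eff.shape[0] - 1))
        assert np.allclose(res.residual_relative_risk().to_numpy(), rr_oracle)
        assert np.allclose(res.spatial_effect_sd().to_numpy(), sd_oracle,
                           atol=1e-12)

    def test_residual_rr_requires_random_effects(self):
        st = small_dataset(seed=9)
        res = BYMModel(st["data"], include_random_effects=False, **FAST,
                       seed=5).fit()
        with pytest.raises(ValueError, match="random effects"):
            res.residual_relative_risk()

    def test_hotspot_shows_in_residual_rr_when_covariate_omitted(self):
        # a cluster elevated through a covariate left out of the fit must
        # surface in exp(u+v)
        st = small_dataset(seed=21, rows=8, cols=8)
        d = st["data"]
        lat = d.lattice
        hot = [a for a in lat.area_ids
               if lat.centroids[a][0] < 113.85 + 3 * 0.03
               and lat.centroids[a][1] < 22.15 + 4 * 0.03]
        hot_idx = [lat.index_of(a) for a in hot]
        rngl = np.random.default_rng(0)
        y = d.y.copy()
        y[hot_idx] = rngl.poisson(d.y[hot_idx] * 2.2)
        d2 = ModelData(y, d.population, d.X, lat)
        res = BYMModel(d2, covariates=("green_space", "populous_grassroots"),
                       **FAST, seed=3).fit()
        rr = res.residual_relative_risk()
        assert rr.iloc[hot_idx].mean() > 1.1
        cold = [i for i in range(lat.n_areas) if i not in hot_idx]
        assert rr.iloc[hot_idx].mean() > rr.iloc[cold].mean()


class TestModelDataValidation:
    def test_misaligned_rejected(self, rook4):
        with pytest.raises(ValueError):
            ModelData(np.ones(3), np.ones(16), pd.DataFrame(np.ones((16, 1))),
                      rook4)

    def test_nonpositive_population_rejected(self, rook4):
        with pytest.raises(ValueError):
            ModelData(np.ones(16), np.zeros(16), pd.DataFrame(np.ones((16, 1))),
                      rook4)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(likelihood="gaussian")
        with pytest.raises(ValueError):
            ModelSpec(burn_in=10, n_iter=10)
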