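"""Synthetic-study generator: lattices, iCAR draws, copula covariates, counts."""

import numpy as np
import pytest

from arealrisk.geometry import augment_links
from arealrisk.simulate import (COVARIATE_RANGES, SimulationConfig,
                                gen_counts, gen_covariates,
                                gen_station_network, icar_pairwise_covariance,
                                make_lattice, sample_icar, simulate_study,
                                suggest_ferry_links)


class TestMakeLattice:
    def test_2x2_queen_counts(self):
        lat = make_lattice(2, 2, 0)
        assert lat.n_areas == 4 and len(lat.edges) == 6

    def test_islands_are_singleton_components(self):
        lat = make_lattice(5, 5, 5, seed=2)
        assert len(lat.components) == 1 + 5
        assert len(lat.singleton_ids()) == 5

    def test_default_scale_emulates_the_study_region(self):
        lat = make_lattice(14, 14, 5, seed=0)
        assert lat.n_areas == 201  # same order as the 214 real subregions
        ferries = suggest_ferry_links(lat)
        assert len(ferries) == 5
        assert len(augment_links(lat, ferries).components) == 1


class TestSampleICAR:
    def test_sum_to_zero_per_component(self):
        lat = make_lattice(6, 6, 3, seed=1)
        u = sample_icar(lat, 0.5, seed=4)
        comp_sums = [sum(u[lat.index_of(a)] for a in comp)
                     for comp in lat.components]
        assert np.abs(comp_sums).max() < 1e-9

    def test_singletons_get_zero(self):
        lat = make_lattice(4, 4, 2, seed=1)
        u = sample_icar(lat, 1.0, seed=0)
        for a in lat.singleton_ids():
            assert u[lat.index_of(a)] == 0.0

    def test_sigma_zero_gives_zero_field(self):
        lat = make_lattice(4, 4, 0)
        assert not sample_icar(lat, 0.0, seed=1).any()

    def test_pairwise_variance_matches_pseudoinverse_oracle(self):
        lat = make_lattice(4, 4, 0)
        sigma2 = 0.8
        cov = icar_pairwise_covariance(lat, sigma2)
        i_idx, j_idx = lat.edge_index_arrays()
        expected = cov[i_idx, i_idx] + cov[j_idx, j_idx] - 2 * cov[i_idx, j_idx]
        rng = np.random.default_rng(12)
        draws = np.array([sample_icar(lat, sigma2, rng=rng) for _ in range(4000)])
        emp = (draws[:, i_idx] - draws[:, j_idx]).var(axis=0)
        assert np.allclose(emp, expected, rtol=0.15)


class TestCovariates:
    def test_identity_target_near_zero_correlations(self):
        X = gen_covariates(10_000, ["indigenous_degree", "family_resilience",
                                    "individual_productivity"], seed=1)
        C = np.corrcoef(X.to_numpy().T)
        off = C[np.triu_indices_from(C, 1)]
        assert np.abs(off).max() < 0.05

    def test_strong_target_recovered(self):
        import pandas as pd
        target = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]],
                              index=["pm25", "pm10"], columns=["pm25", "pm10"])
        X = gen_covariates(10_000, ["pm25", "pm10"], seed=2, target=target)
        r = np.corrcoef(X["pm25"], X["pm10"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_published_ranges_and_greenspace_bounds(self):
        X = gen_covariates(5000, seed=3)
        for name, (lo, hi) in COVARIATE_RANGES.items():
            assert X[name].min() >= lo - 1e-9
            assert X[name].max() <= hi + 1e-9
        assert X["green_space"].between(0, 1).all()

    def test_score_score_correlations_zero_within_mc_error(self):
        X = gen_covariates(10_000, seed=4)
        scores = ["indigenous_degree", "family_resilience",
                  "individual_productivity", "populous_grassroots", "young_age"]
        C = np.corrcoef(X[scores].to_numpy().T)
        assert np.abs(C[np.triu_indices_from(C, 1)]).max() < 0.05


class TestGenCounts:
    def test_poisson_limit_mean(self):
        lat = make_lattice(10, 10, 0)
        X = gen_covariates(100, ["green_space"], seed=5)
        pop = np.full(100, 1e4)
        data, truth = gen_counts(lat, X, -5.0, {}, 0.0, 0.0, 1e13, pop, seed=6)
        assert data.y.mean() == pytest.approx(1e4 * np.exp(-5.0), rel=0.05)

    def test_nb_variance_moment_check(self):
        lat = make_lattice(30, 34, 0)  # many areas for a stable moment
        n = lat.n_areas
        X = gen_covariates(n, ["green_space"], seed=7)
        pop = np.full(n, 2e4)
        data, truth = gen_counts(lat, X, -5.1, {}, 0.0, 0.0, 2.0, pop, seed=8)
        mu = float(truth["mu"][0])
        assert np.allclose(truth["mu"], mu)
        assert data.y.var() == pytest.approx(mu + mu ** 2 / 2.0, rel=0.15)

    def test_generated_data_pass_model_preconditions(self):
        st = simulate_study(SimulationConfig(rows=6, cols=6, n_islands=2, seed=9))
        d = st["data"]
        assert (d.y >= 0).all() and (d.population > 0).all()
        assert np.isfinite(d.X.to_numpy()).all()
        assert d.lattice.n_areas == len(d.y)

    def test_overflow_signalled(self):
        lat = make_lattice(2, 2, 0)
        X = gen_covariates(4, ["green_space"], seed=1)
        with pytest.raises(OverflowError):
            gen_counts(lat, X, 100.0, {}, 0.0, 0.0, 5.0, np.full(4, 1e6), seed=1)


class TestStations:
    def test_deliberate_violations_and_determinism(self):
        bbox = (113.8, 22.1, 114.4, 22.6)
        s1 = gen_station_network(13, bbox, seed=10)
        s2 = gen_station_network(13, bbox, seed=10)
        assert s1[0].altitude_m > 200
        assert s1[1].missing_fraction > 0.25
        for a, b in zip(s1, s2):
            assert a.station_id == b.station_id
            assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_every_area_assigned_after_filtering(self):
        from arealrisk.exposure import assign_nearest, filter_stations
        lat = make_lattice(8, 8, 2, seed=3)
        bbox = (113.85, 22.1, 114.3, 22.6)
        stations = gen_station_network(13, bbox, seed=11)
        kept = filter_stations(stations)
        asg = assign_nearest(lat.centroids, kept)
        assert len(asg.frame) == lat.n_areas
        assert (asg.frame["distance_km"] >= 0).all()


def test_end_to_end_determinism():
    a = simulate_study(SimulationConfig(rows=5, cols=5, n_islands=1, seed=42))
    b = simulate_study(SimulationConfig(rows=5, cols=5, n_islands=1, seed=42))
    assert np.array_equal(a["data"].y, b["data"].y)
    assert a["covariates"].equals(b["covariates"])
    assert np.array_equal(a["landuse"].codes, b["landuse"].codes)
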