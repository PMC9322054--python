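"""Screening, selection, structural comparison and sensitivity rerun."""

import numpy as np
import pandas as pd
import pytest

from arealrisk.bym import ModelSpec
from arealrisk.simulate import SimulationConfig, simulate_study
from arealrisk.workflow import (derive_seed, multivariable_fit, run_selection,
                                sensitivity_rerun, structural_comparisons,
                                univariable_screen)

FAST = ModelSpec(n_chains=1, n_iter=1500, burn_in=600, thin=2, seed=7)


def study(seed=1, **kw):
    defaults = dict(rows=8, cols=8, n_islands=0,
                    covariates=("green_space", "populous_grassroots", "no2",
                                "min_temperature"))
    defaults.update(kw)
    return simulate_study(SimulationConfig(seed=seed, **defaults))


class TestSeedPolicy:
    def test_derived_seeds_stable_and_distinct(self):
        s1 = derive_seed(5, "deaths", "screen", "green_space")
        s2 = derive_seed(5, "deaths", "screen", "green_space")
        s3 = derive_seed(5, "deaths", "screen", "no2")
        assert s1 == s2 != s3
        assert 0 <= s1 < 2**31


class TestScreen:
    def test_schema_and_true_effect_found(self):
        st = study(seed=2)
        table = univariable_screen(st["data"], ["green_space", "no2"], FAST,
                                   outcome="deaths", master_seed=3)
        f = table.frame
        assert list(f["covariate"]) == ["green_space", "no2"]
        assert set(f.columns) >= {"mean", "lower", "upper", "significant",
                                  "dic", "status"}
        assert (f["status"] == "ok").all()
        gs = f.set_index("covariate").loc["green_space"]
        assert gs["significant"] and gs["mean"] < 0
        # flags must be consistent with the CI bounds
        for _, row in f.iterrows():
            assert row["significant"] == (row["lower"] > 0 or row["upper"] < 0)

    def test_failed_fit_marked_and_screen_continues(self, monkeypatch):
        import arealrisk.workflow as wf

        st = study(seed=2)
        real_fit = wf.BYMModel.fit

        def exploding(self, **kw):
            if self.spec.covariates == ("no2",):
                raise RuntimeError("boom")
            return real_fit(self, **kw)

        monkeypatch.setattr(wf.BYMModel, "fit", exploding)
        table = univariable_screen(st["data"], ["green_space", "no2"], FAST)
        f = table.frame.set_index("covariate")
        assert f.loc["no2", "status"] == "failed"
        assert not f.loc["no2", "significant"]
        assert f.loc["green_space", "status"] == "ok"
        assert "no2" not in table.selected()

    def test_power_for_strong_true_effect(self):
        # the generator's default green-space effect must be detectable in
        # most replicates at n=64 areas
        hits = 0
        for rep in range(5):
            st = study(seed=100 + rep)
            t = univariable_screen(st["data"], ["green_space"], FAST,
                                   master_seed=rep)
            hits += bool(t.frame["significant"].iloc[0])
        assert hits >= 4


class TestSelection:
    def test_multivariable_on_selected_only_and_delta_dic_identity(self):
        st = study(seed=3)
        covs = ["green_space", "populous_grassroots", "min_temperature"]
        report = run_selection(st["data"], covs, FAST, outcome="deaths",
                               master_seed=11)
        assert set(report.selected) <= set(covs)
        if report.multivariable is not None:
            assert list(report.multivariable["covariate"]) == report.selected
            assert report.delta_dic == pytest.approx(
                report.dic_multivariable - report.dic_baseline, abs=1e-12)
            # covariates that explain risk must reduce DIC vs the baseline
            assert report.delta_dic < 0
        assert set(report.screen.frame["covariate"]) == set(covs)

    def test_nothing_selected_reports_baseline_only(self):
        st = study(seed=4, beta={})  # all covariates pure noise
        screen = univariable_screen(st["data"], ["no2"], FAST, master_seed=1)
        screen.frame["significant"] = False
        report = multivariable_fit(st["data"], screen, FAST, master_seed=1)
        assert report.selected == [] and report.multivariable is None
        assert report.delta_dic is None and report.dic_baseline > 0

    def test_selection_deterministic(self):
        st = study(seed=5)
        covs = ["green_space", "no2"]
        r1 = run_selection(st["data"], covs, FAST, master_seed=9)
        r2 = run_selection(st["data"], covs, FAST, master_seed=9)
        pd.testing.assert_frame_equal(r1.screen.frame, r2.screen.frame)
        assert r1.selected == r2.selected
        assert r1.delta_dic == r2.delta_dic


class TestStructural:
    def test_schema_and_honest_directional_orderings(self):
        # overdispersed clustered data: the DIC table must show that random
        # effects beat their absence within each likelihood, and that NB
        # beats Poisson when no random effect can soak up overdispersion
        st = study(seed=6, alpha=5.0, sigma_u2=0.3)
        tab = structural_comparisons(st["data"],
                                     ("green_space", "populous_grassroots"),
                                     FAST)
        assert len(tab) == 4 and tab["preferred"].sum() == 1
        t = tab.set_index(["likelihood", "random_effects"])["dic"]
        assert t[("negative_binomial", True)] < t[("negative_binomial", False)]
        assert t[("poisson", True)] < t[("poisson", False)]
        assert t[("negative_binomial", False)] < t[("poisson", False)]

    def test_equidispersed_unclustered_prefers_poisson(self):
        st = study(seed=7, alpha=1e12, sigma_u2=0.0, sigma_v2=0.0,
                   beta={"green_space": -0.5})
        tab = structural_comparisons(st["data"], ("green_space",), FAST)
        best = tab.loc[tab["preferred"]].iloc[0]
        assert best["likelihood"] == "poisson"


class TestSensitivity:
    def test_identical_alternates_reproduce_coefficients(self):
        st = study(seed=8)
        d = st["data"]
        out = sensitivity_rerun(
            d, {"no2": d.X["no2"].to_numpy()}, FAST,
            screen_covariates=["green_space", "no2"], master_seed=13)
        ok = out.dropna(subset=["coef_main", "coef_alternate"])
        assert len(ok) >= 1
        assert np.allclose(ok["coef_main"], ok["coef_alternate"])
        assert ok["sign_agrees"].all()

    def test_small_perturbation_preserves_signs(self):
        st = study(seed=9)
        d = st["data"]
        rng = np.random.default_rng(5)
        alt = d.X["green_space"].to_numpy() + rng.normal(0, 0.01, len(d.X))
        out = sensitivity_rerun(d, {"green_space": np.clip(alt, 0, 1)}, FAST,
                                screen_covariates=["green_space",
                                                   "populous_grassroots"],
                                master_seed=17)
        ok = out.dropna(subset=["coef_main", "coef_alternate"])
        assert ok["sign_agrees"].all()
        assert ((ok["magnitude_ratio"] > 0.5) & (ok["magnitude_ratio"] < 2)).all()

    def test_unknown_covariate_rejected(self):
        st = study(seed=8)
        with pytest.raises(ValueError, match="unknown"):
            sensitivity_rerun(st["data"], {"nope": np.zeros(64)}, FAST)
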