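"""Model-selection workflow.

The selection procedure mirrors the standard small-area practice: for each
mortality outcome, fit one univariable BYM model per candidate covariate
(intercept + offset + random effects + that covariate), keep the covariates
whose 95% credible interval excludes zero, fit the multivariable model on
the kept set, and report the DIC improvement over the covariate-free
baseline (intercept + offset + random effects). Structural comparisons
(with/without random effects, NB vs Poisson) and a sensitivity rerun with
alternate-year exposures round out the procedure.

No multiple-testing correction is applied in screening — a documented
caveat of the procedure, faithfully reproduced rather than silently fixed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bym import BYMModel, BYMResults, ModelData, ModelSpec

__all__ = [
    "ScreenTable",
    "SelectionReport",
    "derive_seed",
    "univariable_screen",
    "multivariable_fit",
    "structural_comparisons",
    "sensitivity_rerun",
    "run_selection",
]

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, *labels: str) -> int:
    """Deterministic sub-seed from the master seed and string labels.

    Every sub-fit of the workflow gets its own reproducible stream; the
    derivation is stable across platforms (SHA-256, not ``hash()``).
    """
    h = hashlib.sha256(("|".join([str(master_seed), *labels])).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class ScreenTable:
    """Univariable screening results: one row per candidate covariate."""

    outcome: str
    frame: pd.DataFrame  # covariate, mean, lower, upper, significant, dic, status

    def selected(self) -> list[str]:
        f = self.frame
        return list(f.loc[(f["status"] == "ok") & f["significant"], "covariate"])


@dataclass
class SelectionReport:
    """Full per-outcome selection record."""

    outcome: str
    screen: ScreenTable
    selected: list[str]
    multivariable: pd.DataFrame | None
    dic_baseline: float
    dic_multivariable: float | None
    delta_dic: float | None
    baseline_fit: BYMResults = field(repr=False)
    multivariable_fit: BYMResults | None = field(default=None, repr=False)
    structural: pd.DataFrame | None = None
    sensitivity: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "selected": self.selected,
            "dic_baseline": self.dic_baseline,
            "dic_multivariable": self.dic_multivariable,
            "delta_dic": self.delta_dic,
            "screen": self.frame_records(self.screen.frame),
            "multivariable": (self.frame_records(self.multivariable)
                              if self.multivariable is not None else None),
        }
        if self.structural is not None:
            d["structural"] = self.frame_records(self.structural)
        if self.sensitivity is not None:
            d["sensitivity"] = self.frame_records(self.sensitivity)
        return d

    @staticmethod
    def frame_records(frame: pd.DataFrame) -> list[dict]:
        return frame.replace({np.nan: None}).to_dict(orient="records")


def _coef_row(res: BYMResults, covariate: str) -> dict:
    s = res.summary_frame.loc[covariate]
    return {"covariate": covariate, "mean": float(s["mean"]),
            "lower": float(s["2.5%"]), "upper": float(s["97.5%"]),
            "significant": bool(s["significant"]), "dic": res.dic_components["DIC"]}


def univariable_screen(data: ModelData, covariates: Sequence[str],
                       spec: ModelSpec, outcome: str = "outcome",
                       master_seed: int | None = None) -> ScreenTable:
    """Fit one single-covariate model per candidate and tabulate.

    Each sub-fit's seed is derived from the master seed (default: the
    spec's) and the covariate/outcome labels. A failed fit marks its row
    ``failed`` (treated as not significant) and screening continues.
    """
    master = spec.seed if master_seed is None else master_seed
    rows = []
    for cov in covariates:
        sub = replace(spec, covariates=(cov,),
                      seed=derive_seed(master, outcome, "screen", cov))
        try:
            res = BYMModel(data, sub).fit()
            row = _coef_row(res, cov)
            row["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - screening must continue
            log.warning("univariable fit failed for %s: %s", cov, exc)
            row = {"covariate": cov, "mean": np.nan, "lower": np.nan,
                   "upper": np.nan, "significant": False, "dic": np.nan,
                   "status": "failed"}
        rows.append(row)
    return ScreenTable(outcome, pd.DataFrame(rows))


def _baseline_fit(data: ModelData, spec: ModelSpec, outcome: str, master: int) -> BYMResults:
    base = replace(spec, covariates=(), seed=derive_seed(master, outcome, "baseline"))
    return BYMModel(data, base).fit()


def multivariable_fit(data: ModelData, screen: ScreenTable, spec: ModelSpec,
                      master_seed: int | None = None) -> SelectionReport:
    """Joint fit on the screened-in covariates, with DIC vs the baseline.

    If nothing screened in, only the baseline (intercept + offset + random
    effects) is reported. delta_dic = DIC_multivariable - DIC_baseline;
    negative values mean the covariates explain part of the spatial
    variability in risk.
    """
    master = spec.seed if master_seed is None else master_seed
    outcome = screen.outcome
    base_res = _baseline_fit(data, spec, outcome, master)
    selected = screen.selected()
    if not selected:
        log.info("%s: no covariate screened in; baseline only", outcome)
        return SelectionReport(outcome, screen, [], None,
                               base_res.dic_components["DIC"], None, None,
                               baseline_fit=base_res)
    multi = replace(spec, covariates=tuple(selected),
                    seed=derive_seed(master, outcome, "multivariable"))
    res = BYMModel(data, multi).fit()
    frame = pd.DataFrame([_coef_row(res, c) for c in selected])
    dic_b = base_res.dic_components["DIC"]
    dic_m = res.dic_components["DIC"]
    return SelectionReport(outcome, screen, selected, frame, dic_b, dic_m,
                           dic_m - dic_b, baseline_fit=base_res,
                           multivariable_fit=res)


def structural_comparisons(data: ModelData, selected: Sequence[str],
                           spec: ModelSpec, outcome: str = "outcome",
                           master_seed: int | None = None) -> pd.DataFrame:
    """DIC for the four structural variants of the selected model.

    Negative binomial vs Poisson crossed with random effects on/off, under
    a shared seed policy; the DIC-minimising variant is flagged preferred.
    """
    master = spec.seed if master_seed is None else master_seed
    rows = []
    for lik in ("negative_binomial", "poisson"):
        for re_on in (True, False):
            label = f"{lik}|re={re_on}"
            sub = replace(spec, covariates=tuple(selected), likelihood=lik,
                          include_random_effects=re_on,
                          seed=derive_seed(master, outcome, "structure", label))
            res = BYMModel(data, sub).fit()
            rows.append({"likelihood": lik, "random_effects": re_on,
                         "dic": res.dic_components["DIC"],
                         "pd": res.dic_components["pD"]})
    frame = pd.DataFrame(rows)
    frame["preferred"] = frame["dic"] == frame["dic"].min()
    return frame


def sensitivity_rerun(data: ModelData, alternate_exposures: Mapping[str, np.ndarray],
                      spec: ModelSpec, screen_covariates: Sequence[str] | None = None,
                      outcome: str = "outcome",
                      master_seed: int | None = None) -> pd.DataFrame:
    """Re-run the screen + multivariable pipeline with exposures swapped.

    ``alternate_exposures`` maps covariate names to replacement per-area
    columns (e.g. the prior year's annual means). Returns a side-by-side
    coefficient table with sign agreement and magnitude ratios.
    """
    master = spec.seed if master_seed is None else master_seed
    covs = list(screen_covariates) if screen_covariates else list(data.X.columns)
    screen_main = univariable_screen(data, covs, spec, outcome, master)
    report_main = multivariable_fit(data, screen_main, spec, master)

    X_alt = data.X.copy()
    for name, col in alternate_exposures.items():
        if name not in X_alt.columns:
            raise ValueError(f"unknown covariate {name!r}")
        col = np.asarray(col, dtype=float)
        if len(col) != len(X_alt):
            raise ValueError(f"alternate column {name!r} does not align with areas")
        X_alt[name] = col
    data_alt = ModelData(data.y, data.population, X_alt, data.lattice)
    screen_alt = univariable_screen(data_alt, covs, spec, outcome, master)
    report_alt = multivariable_fit(data_alt, screen_alt, spec, master)

    def coef_map(report):
        if report.multivariable is None:
            return {}
        return dict(zip(report.multivariable["covariate"], report.multivariable["mean"]))

    main_c, alt_c = coef_map(report_main), coef_map(report_alt)
    rows = []
    for cov in sorted(set(main_c) | set(alt_c)):
        b0, b1 = main_c.get(cov, np.nan), alt_c.get(cov, np.nan)
        rows.append({
            "covariate": cov, "coef_main": b0, "coef_alternate": b1,
            "sign_agrees": bool(np.sign(b0) == np.sign(b1))
            if np.isfinite(b0) and np.isfinite(b1) else None,
            "magnitude_ratio": (abs(b1) / abs(b0))
            if np.isfinite(b0) and np.isfinite(b1) and b0 != 0 else np.nan,
        })
    return pd.DataFrame(rows)


def run_selection(data: ModelData, covariates: Sequence[str], spec: ModelSpec,
                  outcome: str = "outcome", master_seed: int | None = None,
                  with_structural: bool = False) -> SelectionReport:
    """Screen, select, fit and (optionally) compare structures in one call."""
    master = spec.seed if master_seed is None else master_seed
    screen = univariable_screen(data, covariates, spec, outcome, master)
    report = multivariable_fit(data, screen, spec, master)
    if with_structural:
        report.structural = structural_comparisons(
            data, report.selected, spec, outcome, master)
    return report
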