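"""Published reference values from the Hong Kong small-area mortality analysis.

The motivating 2016 Hong Kong tertiary-planning-unit analysis published
posterior-mean regression coefficients (and 95% credible intervals) for four
mortality outcomes, together with city-wide case counts. The underlying
mortality and census data are restricted, so these printed estimates serve
as inputs to the worked examples: the effect-size transforms
(:func:`arealrisk.bym.rr_per_unit`, :func:`arealrisk.bym.percent_change`)
applied to them reproduce the published relative risks and percent changes.

Coefficients are on native covariate scales; green-space density enters as
a fraction in [0, 1], so a 10-percentage-point increase is ``delta = 0.1``.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["CASE_COUNTS", "MORAN_I_NONACCIDENTAL", "multivariable_coefficients",
           "univariable_coefficients"]

# City-wide 2016 case counts by cause group.
CASE_COUNTS: dict[str, int] = {
    "non_accidental": 44_543,
    "cancer": 14_175,
    "respiratory": 10_682,
    "cardiovascular": 9_969,
}

# Global Moran's I reported for 2016 non-accidental mortality rates.
MORAN_I_NONACCIDENTAL = 0.11

# (outcome, covariate) -> (posterior mean, 2.5%, 97.5%), multivariable models.
_MULTI = {
    ("non_accidental", "intercept"): (-6.756, -12.788, -0.748),
    ("non_accidental", "populous_grassroots"): (0.443, 0.313, 0.757),
    ("non_accidental", "young_age"): (-0.429, -0.553, -0.305),
    ("non_accidental", "no2"): (0.011, -0.004, 0.026),
    ("non_accidental", "min_temperature"): (0.034, -0.259, 0.326),
    ("non_accidental", "green_space"): (-0.492, -0.944, -0.041),
    ("cancer", "intercept"): (-8.04, -13.781, -2.339),
    ("cancer", "family_resilience"): (-0.084, -0.213, 0.045),
    ("cancer", "populous_grassroots"): (0.437, 0.314, 0.561),
    ("cancer", "young_age"): (-0.384, -0.502, -0.267),
    ("cancer", "no2"): (0.010, -0.004, 0.023),
    ("cancer", "min_temperature"): (0.044, -0.234, 0.323),
    ("cancer", "green_space"): (-0.342, -0.795, 0.108),
    ("respiratory", "intercept"): (-9.09, -17.18, -1.042),
    ("respiratory", "indigenous_degree"): (0.115, -0.046, 0.279),
    ("respiratory", "family_resilience"): (-0.049, -0.214, 0.119),
    ("respiratory", "individual_productivity"): (-0.227, -0.387, -0.067),
    ("respiratory", "populous_grassroots"): (0.347, 0.191, 0.508),
    ("respiratory", "young_age"): (-0.404, -0.551, -0.260),
    ("respiratory", "no2"): (0.013, -0.004, 0.031),
    ("respiratory", "min_temperature"): (-0.073, -0.320, 0.467),
    ("respiratory", "green_space"): (-0.552, -0.836, -0.268),
    ("cardiovascular", "intercept"): (-6.416, -12.344, -0.500),
    ("cardiovascular", "populous_grassroots"): (0.411, 0.281, 0.545),
    ("cardiovascular", "young_age"): (-0.384, -0.510, -0.260),
    ("cardiovascular", "no2"): (0.010, -0.004, 0.025),
    ("cardiovascular", "min_temperature"): (-0.048, -0.336, 0.240),
    ("cardiovascular", "green_space"): (-0.592, -1.045, -0.141),
}

# Univariable screening estimates for the covariates discussed in the text.
_UNI = {
    ("non_accidental", "populous_grassroots"): (0.487, 0.350, 0.626),
    ("non_accidental", "young_age"): (-0.427, -0.56, -0.29),
    ("non_accidental", "no2"): (0.026, 0.006, 0.045),
    ("non_accidental", "min_temperature"): (0.562, 0.206, 0.918),
    ("non_accidental", "green_space"): (-0.860, -1.396, -0.328),
    ("cancer", "green_space"): (-0.781, -1.278, -0.291),
    ("respiratory", "populous_grassroots"): (0.432, 0.273, 0.596),
    ("cardiovascular", "green_space"): (-0.883, -1.395, -0.379),
}

# DIC of the multivariable model minus that of the intercept+offset+random
# effects baseline, per outcome.
DELTA_DIC: dict[str, float] = {
    "non_accidental": -38.0,
    "cancer": -47.2,
    "respiratory": -32.1,
    "cardiovascular": -36.4,
}


def _to_frame(table: dict) -> pd.DataFrame:
    rows = [{"outcome": o, "covariate": c, "mean": m, "lower": lo, "upper": hi}
            for (o, c), (m, lo, hi) in table.items()]
    return pd.DataFrame(rows)


def multivariable_coefficients() -> pd.DataFrame:
    """Published multivariable posterior means with 95% CI, all outcomes."""
    return _to_frame(_MULTI)


def univariable_coefficients() -> pd.DataFrame:
    """Published univariable posterior means with 95% CI (selected rows)."""
    return _to_frame(_UNI)
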