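"""Global Moran's I and Moran-scatterplot diagnostics.

Moran's I measures global spatial autocorrelation of an areal variable:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z_i = x_i - xbar.

Under the randomization null its expectation is -1/(n-1); both the analytic
randomization variance and a permutation null are provided. The Moran
scatterplot (spatial lag against centred value) classifies areas into
High-High / Low-Low clusters and High-Low / Low-High outliers and, through
an OLS fit whose slope equals I under row-standardised weights, flags areas
with undue influence on the global statistic using standard single-case
regression diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.outliers_influence import OLSInfluence

from .geometry import WeightMatrix

__all__ = [
    "MoranResult",
    "MoranPlotDiagnostics",
    "ZeroVarianceError",
    "morans_i",
    "permutation_test",
    "moran_scatter",
]


class ZeroVarianceError(ValueError):
    """The variable is constant: Moran's I is undefined."""


@dataclass
class MoranResult:
    I: float
    expected_i: float
    variance: float
    z_score: float
    p_analytic: float  # one-sided (greater), randomization moments
    p_permutation: float | None
    n_perm: int
    seed: int | None
    n: int
    dropped_ids: tuple[str, ...]


@dataclass
class MoranPlotDiagnostics:
    """Per-area scatterplot quantities, quadrants and influence flags."""

    frame: pd.DataFrame
    slope: float
    intercept: float
    cutoffs: dict[str, float]


def _prepare(values, weights: WeightMatrix):
    """Align values with the lattice, dropping zero-neighbour areas."""
    lat = weights.lattice
    if isinstance(values, pd.Series):
        x = values.reindex(lat.area_ids).to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if len(x) != lat.n_areas:
            raise ValueError("values length does not match lattice")
    dropped = weights.zero_neighbor_ids
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-neighbour area(s) from Moran's I: "
            f"{list(dropped)}", stacklevel=3)
        keep = np.array([a not in set(dropped) for a in lat.area_ids])
        idx = np.where(keep)[0]
        W = weights.W[np.ix_(idx, idx)].tocsr()
        x = x[keep]
        ids = tuple(a for a in lat.area_ids if a not in set(dropped))
    else:
        W = weights.W
        ids = lat.area_ids
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    return x, W, ids, dropped


def _moran_stat(z, W, S0):
    n = len(z)
    return (n / S0) * float(z @ (W @ z)) / float(z @ z)


def morans_i(values, weights: WeightMatrix) -> MoranResult:
    """Global Moran's I with analytic randomization moments.

    Requires n >= 3 non-constant values; zero-neighbour areas are dropped
    with a warning. The analytic p-value is one-sided (greater), matching
    the permutation test's direction.
    """
    x, W, ids, dropped = _prepare(values, weights)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 areas with neighbours")
    z = x - x.mean()
    ssz = float(z @ z)
    if ssz == 0:
        raise ZeroVarianceError("zero variance: all values equal")
    S0 = float(W.sum())
    I = _moran_stat(z, W, S0)

    # randomization moments
    Wd = W.toarray()
    S1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
    rs = Wd.sum(axis=1)
    cs = Wd.sum(axis=0)
    S2 = float(((rs + cs) ** 2).sum())
    EI = -1.0 / (n - 1)
    b2 = n * float((z ** 4).sum()) / ssz ** 2
    if n > 3:
        num = (n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
               - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0))
        den = (n - 1) * (n - 2) * (n - 3) * S0 * S0
        VI = num / den - EI * EI
    else:
        VI = np.nan  # randomization variance needs n >= 4
    zscore = (I - EI) / np.sqrt(VI) if np.isfinite(VI) and VI > 0 else np.nan
    p_analytic = float(norm.sf(zscore)) if np.isfinite(zscore) else np.nan
    p_analytic = min(max(p_analytic, np.nextafter(0, 1)), 1.0)
    return MoranResult(I, EI, VI, float(zscore), p_analytic,
                       None, 0, None, n, tuple(dropped))


def permutation_test(values, weights: WeightMatrix, n_perm: int = 999,
                     seed: int | None = None) -> MoranResult:
    """Permutation null for Moran's I.

    One-sided (greater) p = (1 + #{I_perm >= I_obs}) / (1 + n_perm); the
    attainable resolution is 1/(n_perm+1). Reproducible for a fixed seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    res = morans_i(values, weights)
    x, W, _, _ = _prepare(values, weights)
    z = x - x.mean()
    S0 = float(W.sum())
    rng = np.random.default_rng(seed)
    n = len(z)
    # permute in blocks to vectorise the quadratic form
    count = 0
    block = 256
    done = 0
    denom = float(z @ z)  # invariant under permutation
    while done < n_perm:
        b = min(block, n_perm - done)
        Zp = np.empty((n, b))
        for k in range(b):
            Zp[:, k] = z[rng.permutation(n)]
        stats = (n / S0) * np.einsum("ik,ik->k", Zp, W @ Zp) / denom
        count += int((stats >= res.I - 1e-15).sum())
        done += b
    p_perm = (1 + count) / (1 + n_perm)
    res.p_permutation = p_perm
    res.n_perm = n_perm
    res.seed = seed
    return res


def moran_scatter(values, weights: WeightMatrix) -> MoranPlotDiagnostics:
    """Moran scatterplot quadrants and OLS influence diagnostics.

    The spatial lag (weighted mean of neighbours' centred values, with
    row-standardised weights) is regressed on the centred value; the slope
    of that line equals Moran's I. Areas exceeding any conventional
    single-case cutoff (leverage > 2(k+1)/n, |DFFITS| > 2 sqrt((k+1)/n),
    Cook's D > 4/n, |studentised residual| > 2) are flagged influential.

    Areas exactly at the global mean are labelled "Low" on the value axis
    (deterministic tie rule); the same rule applies to the lag axis.
    """
    if weights.style != "row_standardized":
        raise ValueError("moran_scatter requires row-standardised weights")
    x, W, ids, dropped = _prepare(values, weights)
    z = x - x.mean()
    if float(z @ z) == 0:
        raise ZeroVarianceError("zero variance: all values equal")
    lag = W @ z
    design = sm.add_constant(z)
    ols = sm.OLS(lag, design).fit()
    infl = OLSInfluence(ols)
    n, k = len(z), 1
    cutoffs = {
        "leverage": 2 * (k + 1) / n,
        "dffits": 2 * np.sqrt((k + 1) / n),
        "cooks_d": 4 / n,
        "studentized": 2.0,
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        # a perfect fit (e.g. checkerboard) has zero residual variance;
        # studentised measures are NaN there and simply never flag
        lev = infl.hat_matrix_diag
        stud = infl.resid_studentized_external
        dffits = infl.dffits[0]
        cooks = infl.cooks_distance[0]
    flagged = ((lev > cutoffs["leverage"]) | (np.abs(dffits) > cutoffs["dffits"])
               | (cooks > cutoffs["cooks_d"]) | (np.abs(stud) > cutoffs["studentized"]))
    value_side = np.where(z > 0, "High", "Low")
    lag_side = np.where(lag > 0, "High", "Low")
    quadrant = np.char.add(np.char.add(value_side, "-"), lag_side)
    frame = pd.DataFrame({
        "area_id": list(ids),
        "value": x,
        "centered": z,
        "lag": lag,
        "quadrant": quadrant,
        "leverage": lev,
        "studentized": stud,
        "dffits": dffits,
        "cooks_d": cooks,
        "influential": flagged,
    })
    return MoranPlotDiagnostics(frame, float(ols.params[1]), float(ols.params[0]),
                                cutoffs)


def plot_moran_scatter(diag: MoranPlotDiagnostics, ax=None):
    """Render the Moran scatterplot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    f = diag.frame
    ax.scatter(f["centered"], f["lag"], c=np.where(f["influential"], "C3", "C0"), s=18)
    xs = np.linspace(f["centered"].min(), f["centered"].max(), 2)
    ax.plot(xs, diag.intercept + diag.slope * xs, "k-", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("centred value")
    ax.set_ylabel("spatial lag")
    ax.set_title(f"Moran scatterplot (slope = {diag.slope:.3f})")
    return ax
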