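"""Bayesian BYM disease mapping: negative-binomial areal regression.

The model for annual death counts Y_i in areas i = 1..n is

    Y_i ~ NB(mu_i, alpha)                       (NB2: Var = mu + mu^2/alpha)
    log(mu_i) = beta_0 + X_i beta + log(population_i) + u_i + v_i
    u ~ iCAR(sigma_u^2)      conditionally u_i | u_-i ~ N(ubar_i, sigma_u^2/n_i)
    v_i ~ N(0, sigma_v^2)

with a log-population offset so the regression describes mortality rates,
a spatially structured random effect u (intrinsic conditional autoregressive
prior on the adjacency lattice, sum-to-zero per connected component) and an
exchangeable unstructured effect v. A Poisson likelihood is available as the
alpha -> infinity limit for structural comparison.

Priors are vague by default: beta ~ N(0, 1e6), sigma_u^2 and sigma_v^2 ~
InverseGamma(0.01, 0.01), alpha ~ Gamma(0.01, 0.01); all configurable.

Inference is Metropolis-within-Gibbs MCMC: adaptive random-walk updates for
beta and alpha, graph-coloured parallel single-site random-walk updates for
u, vectorised independent updates for v, and conjugate inverse-gamma draws
for the two variances. u is re-centred to sum to zero per connected
component after every sweep; the intercept absorbs the overall level. Model
fit is summarised by the deviance information criterion
DIC = Dbar + pD, pD = Dbar - D(posterior means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geometry import AreaLattice

__all__ = [
    "ModelData",
    "ModelSpec",
    "BYMModel",
    "BYMResults",
    "DivergenceError",
    "nb_log_likelihood",
    "linear_predictor",
    "icar_logpdf_and_conditionals",
    "rr_per_unit",
    "percent_change",
]


class DivergenceError(RuntimeError):
    """The sampler reached a non-finite posterior state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------------
# likelihood pieces


def _nb_ll_vec(y, mu, alpha):
    """Per-observation NB2 log-pmf, mean mu, shape alpha (no validation)."""
    return (gammaln(y + alpha) - gammaln(alpha) - gammaln(y + 1)
            + alpha * np.log(alpha) + y * np.log(mu)
            - (y + alpha) * np.log(alpha + mu))


def _pois_ll_vec(y, mu):
    return -mu + y * np.log(mu) - gammaln(y + 1)


def nb_log_likelihood(y, mu, alpha) -> float:
    """Summed NB2 log-likelihood with mean ``mu`` and shape ``alpha``.

    Variance is mu + mu^2/alpha; the Poisson log-likelihood is recovered in
    the alpha -> infinity limit. Counts must be non-negative integers and
    mu, alpha strictly positive.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integers")
    if np.any(mu <= 0) or alpha <= 0:
        raise ValueError("mu and alpha must be positive")
    y = np.asarray(y, dtype=float)
    alpha = float(alpha)
    if alpha <= 1e6:
        return float(_nb_ll_vec(y, mu, alpha).sum())
    # large-alpha branch: the gammaln difference cancels catastrophically,
    # so use log1p identities that degrade gracefully into the Poisson limit
    ratio_terms = sum(np.log1p(np.arange(int(yi)) / alpha).sum() for yi in y)
    ll = (ratio_terms - gammaln(y + 1).sum()
          + float((y * np.log(mu) - (alpha + y) * np.log1p(mu / alpha)).sum()))
    return float(ll)


def linear_predictor(beta0, beta, X, log_population, u=None, v=None) -> np.ndarray:
    """log(mu_i) = beta0 + X_i beta + log(population_i) + u_i + v_i."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eta = beta0 + (X @ beta if X.size else 0.0) + np.asarray(log_population, dtype=float)
    if u is not None:
        eta = eta + np.asarray(u, dtype=float)
    if v is not None:
        eta = eta + np.asarray(v, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    return eta


def rr_per_unit(coef: float, delta: float = 1.0) -> float:
    """Relative risk for a ``delta`` change in a covariate: exp(coef*delta)."""
    return float(np.exp(coef * delta))


def percent_change(coef: float, delta: float = 1.0) -> float:
    """Percent decrease (positive) or increase (negative) in risk.

    Returns (1 - exp(coef*delta)) * 100: positive values are decreases, as
    conventionally reported for protective exposures.
    """
    return float((1.0 - np.exp(coef * delta)) * 100.0)


# ---------------------------------------------------------------------------
# iCAR prior


@dataclass
class ICARDensity:
    logpdf: float
    cond_mean: np.ndarray
    cond_var: np.ndarray


def icar_logpdf_and_conditionals(u, lattice: AreaLattice, sigma_u2: float) -> ICARDensity:
    """Intrinsic CAR log-density (up to constant) and full conditionals.

    logpdf = -(1/(2 sigma_u^2)) sum_{i~j} (u_i - u_j)^2
             - ((n* - c)/2) log(sigma_u^2)

    where n* is the number of areas with neighbours and c the number of
    non-singleton components (the rank of the graph Laplacian). The full
    conditional of u_i is N(mean of neighbours, sigma_u^2 / n_i).
    Zero-neighbour areas have their u fixed at 0 (warned if nonzero).
    """
    if sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive")
    u = np.asarray(u, dtype=float)
    deg = lattice.degrees()
    i_idx, j_idx = lattice.edge_index_arrays()
    q = float(((u[i_idx] - u[j_idx]) ** 2).sum())
    n_struct = int((deg > 0).sum())
    n_comp = sum(1 for c in lattice.components if len(c) > 1)
    logpdf = -0.5 * q / sigma_u2 - 0.5 * (n_struct - n_comp) * np.log(sigma_u2)
    W = lattice.adjacency_matrix()
    s = W @ u
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_mean = np.where(deg > 0, s / np.maximum(deg, 1), 0.0)
        cond_var = np.where(deg > 0, sigma_u2 / np.maximum(deg, 1), np.nan)
    if np.any((deg == 0) & (u != 0)):
        warnings.warn("zero-neighbour area has nonzero u; it is fixed at 0 "
                      "in the structured prior", stacklevel=2)
    return ICARDensity(float(logpdf), cond_mean, cond_var)


# ---------------------------------------------------------------------------
# data and spec containers


@dataclass
class ModelData:
    """Aligned counts, populations, covariates and lattice.

    Row order of ``y``, ``population`` and ``X`` follows
    ``lattice.area_ids``.
    """

    y: np.ndarray
    population: np.ndarray
    X: pd.DataFrame
    lattice: AreaLattice

    def __post_init__(self):
        n = self.lattice.n_areas
        self.y = np.asarray(self.y)
        self.population = np.asarray(self.population, dtype=float)
        if len(self.y) != n or len(self.population) != n or len(self.X) != n:
            raise ValueError("y, population and X must align with the lattice")
        if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("y must be non-negative integer counts")
        self.y = np.round(self.y).astype(np.int64)
        if np.any(~np.isfinite(self.population)) or np.any(self.population <= 0):
            raise ValueError("populations must be finite and positive")
        if not np.isfinite(self.X.to_numpy(dtype=float)).all():
            raise ValueError("covariates must be finite")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, lattice: AreaLattice,
                   outcome: str, population: str = "population",
                   covariates: Sequence[str] | None = None) -> "ModelData":
        """Assemble from a per-area table indexed (or keyed) by area_id."""
        df = frame.copy()
        if "area_id" in df.columns:
            df = df.set_index("area_id")
        df.index = df.index.astype(str)
        df = df.loc[list(lattice.area_ids)]
        if covariates is None:
            covariates = [c for c in df.columns if c not in (outcome, population)]
        return cls(df[outcome].to_numpy(), df[population].to_numpy(),
                   df[list(covariates)].astype(float), lattice)


@dataclass(frozen=True)
class ModelSpec:
    """Model structure, priors and MCMC controls."""

    covariates: tuple[str, ...] | None = None  # None = all columns of X
    likelihood: str = "negative_binomial"      # or "poisson"
    include_random_effects: bool = True
    beta_prior_var: float = 1e6
    sigma_prior_shape: float = 0.01
    sigma_prior_rate: float = 0.01
    alpha_prior_shape: float = 0.01
    alpha_prior_rate: float = 0.01
    n_chains: int = 4
    n_iter: int = 15_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.likelihood not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        for name in ("beta_prior_var", "sigma_prior_shape", "sigma_prior_rate",
                     "alpha_prior_shape", "alpha_prior_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


# ---------------------------------------------------------------------------
# the model


class BYMModel:
    """BYM negative-binomial (or Poisson) spatial regression model.

    Parameters
    ----------
    data
        Aligned :class:`ModelData`.
    spec
        :class:`ModelSpec`; keyword overrides are applied on top.

    Examples
    --------
    >>> model = BYMModel(data, covariates=("green_space",), seed=7)
    >>> res = model.fit()
    >>> res.summary()          # doctest: +SKIP
    """

    def __init__(self, data: ModelData, spec: ModelSpec | None = None, **overrides):
        self.data = data
        spec = spec or ModelSpec()
        if overrides:
            spec = replace(spec, **overrides)
        if spec.covariates is None:
            spec = replace(spec, covariates=tuple(data.X.columns))
        missing = [c for c in spec.covariates if c not in data.X.columns]
        if missing:
            raise ValueError(f"covariates not in X: {missing}")
        self.spec = spec

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, lattice: AreaLattice,
                       outcome: str, population: str = "population",
                       covariates: Sequence[str] | None = None, **spec_kw) -> "BYMModel":
        data = ModelData.from_frame(frame, lattice, outcome, population, covariates)
        return cls(data, covariates=tuple(covariates) if covariates else None, **spec_kw)

    # -- sampler infrastructure -------------------------------------------

    def _prepare(self):
        d, s = self.data, self.spec
        lat = d.lattice
        n = lat.n_areas
        Xc = d.X[list(s.covariates)].to_numpy(dtype=float)
        Xf = np.column_stack([np.ones(n), Xc]) if Xc.size else np.ones((n, 1))
        names = ["intercept", *s.covariates]
        logpop = np.log(d.population)
        deg = lat.degrees()
        i_idx, j_idx = lat.edge_index_arrays()
        # colour classes over areas with neighbours: within a class no two
        # areas are adjacent, so their single-site updates commute.
        g = lat.to_graph()
        structured = [a for a in lat.area_ids if lat.neighbor_counts[a] > 0]
        colors = nx.greedy_color(g.subgraph(structured), strategy="largest_first")
        classes: dict[int, list[int]] = {}
        for a, c in colors.items():
            classes.setdefault(c, []).append(lat.index_of(a))
        W = lat.adjacency_matrix()
        color_blocks = []
        for c in sorted(classes):
            idx = np.array(sorted(classes[c]), dtype=int)
            color_blocks.append((idx, W[idx].tocsr()))
        comp_blocks = [np.array(sorted(lat.index_of(a) for a in comp), dtype=int)
                       for comp in lat.components if len(comp) > 1]
        n_struct = int((deg > 0).sum())
        return dict(n=n, Xf=Xf, names=names, logpop=logpop, deg=deg,
                    i_idx=i_idx, j_idx=j_idx, color_blocks=color_blocks,
                    comp_blocks=comp_blocks, n_struct=n_struct,
                    n_comp=len(comp_blocks))

    def fit(self, **overrides) -> "BYMResults":
        """Run the MCMC and return a :class:`BYMResults`.

        Keyword overrides (``n_iter=2000, seed=5`` ...) are applied to the
        spec for this fit only. A fixed seed gives bit-identical chains.
        """
        spec = replace(self.spec, **overrides) if overrides else self.spec
        prep = self._prepare()
        ss = np.random.SeedSequence(spec.seed)
        chains = [self._run_chain(np.random.default_rng(child), spec, prep)
                  for child in ss.spawn(spec.n_chains)]
        return BYMResults(self, spec, prep, chains)

    def _run_chain(self, rng, spec: ModelSpec, prep) -> dict:
        y = self.data.y.astype(float)
        n, Xf, logpop = prep["n"], prep["Xf"], prep["logpop"]
        p = Xf.shape[1]
        nb = spec.likelihood == "negative_binomial"
        re_on = spec.include_random_effects
        deg = prep["deg"].astype(float)
        i_idx, j_idx = prep["i_idx"], prep["j_idx"]
        cy = -gammaln(y + 1)

        # initial state: crude rate intercept, residual-split random effects
        beta = np.zeros(p)
        beta[0] = np.log(y.sum() / self.data.population.sum())
        beta += 0.01 * rng.standard_normal(p)
        alpha = 10.0
        sigma_u2 = sigma_v2 = 0.1
        u = np.zeros(n)
        v = np.zeros(n)
        if re_on:
            resid = np.log((y + 0.5) / self.data.population) - beta[0]
            resid = np.clip(resid - resid.mean(), -2, 2)
            u = np.where(deg > 0, 0.5 * resid, 0.0)
            for comp in prep["comp_blocks"]:
                u[comp] -= u[comp].mean()
            v = 0.2 * resid + 0.01 * rng.standard_normal(n)

        def ga_terms(a):
            return gammaln(y + a) - gammaln(a) + a * np.log(a)

        ga = ga_terms(alpha) if nb else None

        def llvec(mu, a=None):
            if nb:
                g = ga if a is None else ga_terms(a)
                aa = alpha if a is None else a
                return cy + g + y * np.log(mu) - (y + aa) * np.log(aa + mu)
            return cy - mu + y * np.log(mu)

        eta = Xf @ beta + logpop + u + v
        mu = np.exp(eta)
        ll = llvec(mu)
        ll_sum = ll.sum()

        # adaptive proposal scales, frozen after burn-in
        sc_beta = np.full(p, 0.05)
        sc_u, sc_v, sc_alpha = 0.3, 0.3, 0.3
        acc = {"beta": np.zeros(p), "u": 0.0, "u_n": 0.0, "v": 0.0, "v_n": 0.0,
               "alpha": 0.0, "att": 0}
        a_sig, b_sig = spec.sigma_prior_shape, spec.sigma_prior_rate
        c_al, d_al = spec.alpha_prior_shape, spec.alpha_prior_rate
        bvar = spec.beta_prior_var

        n_keep = (spec.n_iter - spec.burn_in) // spec.thin
        out = {
            "beta": np.empty((n_keep, p)),
            "alpha": np.empty(n_keep),
            "sigma_u2": np.empty(n_keep),
            "sigma_v2": np.empty(n_keep),
            "u": np.empty((n_keep, n)),
            "v": np.empty((n_keep, n)),
            "deviance": np.empty(n_keep),
        }
        kept = 0
        for it in range(spec.n_iter):
            adapting = it < spec.burn_in
            # --- beta: per-coordinate random walk
            for k in range(p):
                prop = beta[k] + sc_beta[k] * rng.standard_normal()
                eta_p = eta + Xf[:, k] * (prop - beta[k])
                mu_p = np.exp(eta_p)
                ll_p = llvec(mu_p)
                logr = (ll_p.sum() - ll_sum
                        + (beta[k] ** 2 - prop ** 2) / (2 * bvar))
                if np.log(rng.uniform()) < logr:
                    beta[k] = prop
                    eta, mu, ll, ll_sum = eta_p, mu_p, ll_p, ll_p.sum()
                    acc["beta"][k] += 1
            if re_on:
                # --- u: coloured parallel single-site random walk
                for idx, Wc in prep["color_blocks"]:
                    sN = Wc @ u  # neighbour sums, fixed within the class
                    d_u = sc_u * rng.standard_normal(len(idx))
                    u_new = u[idx] + d_u
                    eta_p = eta[idx] + d_u
                    mu_p = np.exp(eta_p)
                    # per-area proposal log-likelihood on the subset only
                    if nb:
                        ll_p = (cy[idx] + ga[idx] + y[idx] * np.log(mu_p)
                                - (y[idx] + alpha) * np.log(alpha + mu_p))
                    else:
                        ll_p = cy[idx] - mu_p + y[idx] * np.log(mu_p)
                    dprior = -(deg[idx] * (u_new ** 2 - u[idx] ** 2)
                               - 2 * sN * d_u) / (2 * sigma_u2)
                    ok = np.log(rng.uniform(size=len(idx))) < (ll_p - ll[idx] + dprior)
                    w = idx[ok]
                    u[w] = u_new[ok]
                    eta[w] = eta_p[ok]
                    mu[w] = mu_p[ok]
                    ll[w] = ll_p[ok]
                    acc["u"] += ok.sum()
                    acc["u_n"] += len(idx)
                # sum-to-zero re-centring per component; the intercept
                # absorbs the level through its own updates
                shifted = False
                for comp in prep["comp_blocks"]:
                    m = u[comp].mean()
                    if m != 0.0:
                        u[comp] -= m
                        eta[comp] -= m
                        shifted = True
                if shifted:
                    mu = np.exp(eta)
                    ll = llvec(mu)
                ll_sum = ll.sum()
                # --- v: independent vectorised random walk
                d_v = sc_v * rng.standard_normal(n)
                v_new = v + d_v
                eta_p = eta + d_v
                mu_p = np.exp(eta_p)
                ll_p = llvec(mu_p)
                dprior = -(v_new ** 2 - v ** 2) / (2 * sigma_v2)
                ok = np.log(rng.uniform(size=n)) < (ll_p - ll + dprior)
                v[ok] = v_new[ok]
                eta[ok] = eta_p[ok]
                mu[ok] = mu_p[ok]
                ll[ok] = ll_p[ok]
                ll_sum = ll.sum()
                acc["v"] += ok.sum()
                acc["v_n"] += n
                # --- variances: conjugate inverse-gamma
                q = float(((u[i_idx] - u[j_idx]) ** 2).sum())
                shape_u = a_sig + 0.5 * (prep["n_struct"] - prep["n_comp"])
                sigma_u2 = 1.0 / rng.gamma(shape_u, 1.0 / (b_sig + 0.5 * q))
                shape_v = a_sig + 0.5 * n
                sigma_v2 = 1.0 / rng.gamma(shape_v, 1.0 / (b_sig + 0.5 * float(v @ v)))
            if nb:
                # --- alpha: random walk on log scale
                la = np.log(alpha)
                la_p = la + sc_alpha * rng.standard_normal()
                a_p = np.exp(la_p)
                ga_p = ga_terms(a_p)
                ll_p = cy + ga_p + y * np.log(mu) - (y + a_p) * np.log(a_p + mu)
                logr = (ll_p.sum() - ll_sum + c_al * (la_p - la)
                        - d_al * (a_p - alpha))
                if np.log(rng.uniform()) < logr:
                    alpha, ga = a_p, ga_p
                    ll, ll_sum = ll_p, ll_p.sum()
                    acc["alpha"] += 1
            acc["att"] += 1
            if adapting and acc["att"] == 50:
                rate = acc["beta"] / 50
                sc_beta *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
                if re_on:
                    if acc["u_n"]:
                        sc_u *= np.exp(np.clip(acc["u"] / acc["u_n"] - 0.4, -0.5, 0.5))
                    sc_v *= np.exp(np.clip(acc["v"] / acc["v_n"] - 0.4, -0.5, 0.5))
                if nb:
                    sc_alpha *= np.exp(np.clip(acc["alpha"] / 50 - 0.35, -0.5, 0.5))
                acc = {"beta": np.zeros(p), "u": 0.0, "u_n": 0.0, "v": 0.0,
                       "v_n": 0.0, "alpha": 0.0, "att": 0}
            if not np.isfinite(ll_sum):
                raise DivergenceError(
                    "non-finite posterior state",
                    state={"iter": it, "beta": beta.copy(), "alpha": alpha,
                           "sigma_u2": sigma_u2, "sigma_v2": sigma_v2,
                           "max_eta": float(eta.max())})
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and kept < n_keep:
                out["beta"][kept] = beta
                out["alpha"][kept] = alpha
                out["sigma_u2"][kept] = sigma_u2
                out["sigma_v2"][kept] = sigma_v2
                out["u"][kept] = u
                out["v"][kept] = v
                out["deviance"][kept] = -2.0 * ll_sum
                kept += 1
        for key in out:
            out[key] = out[key][:kept]
        return out


# ---------------------------------------------------------------------------
# results


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for one scalar.

    ``chains_draws`` has shape (n_chains, n_draws); each chain is split in
    half before computing the between/within variance ratio.
    """
    halves = []
    for c in chains_draws:
        h = len(c) // 2
        if h < 2:
            return np.nan
        halves.extend([c[:h], c[h:2 * h]])
    a = np.array(halves)
    m, n = a.shape
    means = a.mean(axis=1)
    W = a.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


class BYMResults:
    """Posterior draws, summaries, DIC and derived risk surfaces."""

    RHAT_THRESHOLD = 1.1

    def __init__(self, model: BYMModel, spec: ModelSpec, prep, chains: list[dict]):
        self.model = model
        self.spec = spec
        self._prep = prep
        self.coef_names = prep["names"]
        self.chains = chains
        self.draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
        self._summary = self._summarize()
        self.dic_components = self._dic()

    # -- posterior bookkeeping --------------------------------------------
    def _flat(self, key):
        d = self.draws[key]
        return d.reshape(-1, *d.shape[2:])

    def _summarize(self) -> pd.DataFrame:
        rows = []
        nb = self.spec.likelihood == "negative_binomial"
        re_on = self.spec.include_random_effects
        scalars: list[tuple[str, np.ndarray]] = []
        beta = self.draws["beta"]
        for k, name in enumerate(self.coef_names):
            scalars.append((name, beta[:, :, k]))
        if nb:
            scalars.append(("alpha", self.draws["alpha"]))
        if re_on:
            scalars.append(("sigma_u2", self.draws["sigma_u2"]))
            scalars.append(("sigma_v2", self.draws["sigma_v2"]))
        for name, d in scalars:
            flat = d.reshape(-1)
            lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975])
            rows.append({
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "2.5%": lo,
                "50%": med,
                "97.5%": hi,
                "rhat": _split_rhat(d),
                "significant": bool(lo > 0 or hi < 0) if name in self.coef_names else np.nan,
            })
        return pd.DataFrame(rows).set_index("parameter")

    @property
    def summary_frame(self) -> pd.DataFrame:
        return self._summary

    @property
    def params(self) -> pd.Series:
        """Posterior means of the regression coefficients."""
        return self._summary.loc[self.coef_names, "mean"]

    @property
    def converged(self) -> bool:
        r = self._summary["rhat"].dropna()
        return bool((r < self.RHAT_THRESHOLD).all())

    def significant(self, name: str) -> bool:
        """True if the 95% credible interval excludes zero."""
        return bool(self._summary.loc[name, "significant"])

    # -- DIC ----------------------------------------------------------------
    def _deviance_at(self, beta, u, v, alpha) -> float:
        prep = self._prep
        eta = prep["Xf"] @ beta + prep["logpop"] + u + v
        mu = np.exp(eta)
        y = self.model.data.y
        if self.spec.likelihood == "negative_binomial":
            ll = nb_log_likelihood(y, mu, alpha)
        else:
            ll = float(_pois_ll_vec(y.astype(float), mu).sum())
        return -2.0 * ll

    def _dic(self) -> dict[str, float]:
        dbar = float(self._flat("deviance").mean())
        beta_bar = self._flat("beta").mean(axis=0)
        u_bar = self._flat("u").mean(axis=0)
        v_bar = self._flat("v").mean(axis=0)
        alpha_bar = float(self._flat("alpha").mean())
        d_hat = self._deviance_at(beta_bar, u_bar, v_bar, alpha_bar)
        pd_ = dbar - d_hat
        return {"DIC": dbar + pd_, "Dbar": dbar, "D_hat": d_hat, "pD": pd_}

    @property
    def dic(self) -> float:
        if self._flat("deviance").shape[0] < 100:
            warnings.warn("fewer than 100 retained draws; DIC is noisy", stacklevel=2)
        return self.dic_components["DIC"]

    # -- derived surfaces ---------------------------------------------------
    def fitted_mu(self) -> np.ndarray:
        """Posterior mean of mu_i (averaged over draws)."""
        prep = self._prep
        beta = self._flat("beta")
        u = self._flat("u")
        v = self._flat("v")
        eta = beta @ prep["Xf"].T + prep["logpop"][None, :] + u + v
        return np.exp(eta).mean(axis=0)

    def residual_relative_risk(self) -> pd.Series:
        """Per-area posterior mean of exp(u_i + v_i).

        The risk remaining relative to the study region after the fitted
        covariates are accounted for.
        """
        self._require_random_effects()
        rr = np.exp(self._flat("u") + self._flat("v")).mean(axis=0)
        return pd.Series(rr, index=list(self.model.data.lattice.area_ids),
                         name="residual_rr")

    def spatial_effect_sd(self, transformed: bool = False) -> pd.Series:
        """Per-area posterior SD of u_i + v_i (or of exp(u_i+v_i))."""
        self._require_random_effects()
        eff = self._flat("u") + self._flat("v")
        if transformed:
            eff = np.exp(eff)
        sd = eff.std(axis=0, ddof=1)
        return pd.Series(sd, index=list(self.model.data.lattice.area_ids),
                         name="spatial_effect_sd")

    def _require_random_effects(self):
        if not self.spec.include_random_effects:
            raise ValueError("model was fitted without random effects")

    # -- effect transforms ---------------------------------------------------
    def relative_risk(self, name: str, delta: float = 1.0) -> dict[str, float]:
        """RR (with 95% CI) for a ``delta`` change in covariate ``name``."""
        row = self._summary.loc[name]
        return {"rr": rr_per_unit(row["mean"], delta),
                "lower": rr_per_unit(row["2.5%"], delta),
                "upper": rr_per_unit(row["97.5%"], delta)}

    def percent_change(self, name: str, delta: float = 1.0) -> float:
        return percent_change(float(self._summary.loc[name, "mean"]), delta)

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.spec
        head = (
            f"BYM {'negative-binomial' if s.likelihood == 'negative_binomial' else 'Poisson'}"
            f" spatial regression\n"
            f"areas: {self.model.data.lattice.n_areas}   "
            f"chains: {s.n_chains} x {s.n_iter} (burn {s.burn_in}, thin {s.thin})   "
            f"seed: {s.seed}\n"
            f"random effects: {'iCAR + exchangeable' if s.include_random_effects else 'none'}\n"
            f"DIC: {self.dic_components['DIC']:.1f}  "
            f"(Dbar {self.dic_components['Dbar']:.1f}, pD {self.dic_components['pD']:.1f})   "
            f"converged: {self.converged}\n"
        )
        with pd.option_context("display.width", 120):
            return head + self._summary.round(4).to_string()
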