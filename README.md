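# arealrisk

Small-area Bayesian disease mapping for environmental epidemiology: who dies
where, and how much of the spatial pattern is explained by the built
environment?

`arealrisk` implements the standard analysis pipeline for annual mortality
counts aggregated to small administrative areas (the motivating setting is
Hong Kong's ~214 tertiary planning units): spatial-autocorrelation screening
with Moran's I, nearest-monitor assignment of meteorological and air-quality
exposures, green-space density from a categorical land-use raster, and a
Besag–York–Mollié (BYM) negative-binomial regression with spatially
structured and unstructured random effects, fitted by MCMC. Because the real
mortality and census inputs are restricted, the package ships a first-class
synthetic-study generator that draws data from the model itself, so every
stage is reproducible and testable end to end.

## The model

For areas *i* = 1…*n* with annual death counts *Y_i*, populations, and
area-level covariates *X_i* (socioeconomic principal-component scores,
annual exposure means, green-space density):

```
Y_i ~ NB(mu_i, alpha)                         Var(Y_i) = mu_i + mu_i^2/alpha
log(mu_i) = beta_0 + X_i beta + log(population_i) + u_i + v_i
u_i | u_-i ~ Normal(mean of neighbours' u, sigma_u^2 / n_i)     (iCAR)
v_i ~ Normal(0, sigma_v^2)
```

The log-population offset makes the regression describe mortality *rates*;
`u` is an intrinsic conditional autoregressive (iCAR) field on the
contiguity lattice (sum-to-zero per connected component) capturing spatially
structured risk, and `v` is an exchangeable effect capturing unstructured
heterogeneity. Priors are vague: `beta ~ N(0, 1e6)`, variances
`InverseGamma(0.01, 0.01)`, `alpha ~ Gamma(0.01, 0.01)`. Model selection
follows the univariable-screen → multivariable-fit procedure with the 95%
credible interval as the significance rule and DIC (= Dbar + pD) for fit
comparison. `exp(coef × delta)` converts a coefficient into a relative risk
for a `delta` change of the covariate.

## Worked example

```python
import arealrisk as ar

# a synthetic study: 10x10 queen-contiguity grid, counts drawn from the
# BYM-NB model with known effects and strong spatial clustering
study = ar.simulate_study(ar.SimulationConfig(
    rows=10, cols=10, n_islands=0, sigma_u2=0.3, seed=3,
    covariates=("green_space", "populous_grassroots")))
data = study["data"]

# spatial screening on the crude rate
w = ar.make_weights(data.lattice, "row_standardized")
smr = data.y / data.population
res = ar.permutation_test(smr, w, n_perm=999, seed=1)
print(f"Moran's I = {res.I:.3f}, permutation p = {res.p_permutation:.3f}")

# BYM negative-binomial fit
model = ar.BYMModel(data, covariates=("green_space", "populous_grassroots"),
                    n_chains=2, n_iter=6000, burn_in=2500, thin=2, seed=42)
fit = model.fit()
print(fit.summary())
print("RR per +10 points of green space:",
      round(fit.relative_risk("green_space", 0.1)["rr"], 3))
```

prints

```
Moran's I = 0.171, permutation p = 0.003
BYM negative-binomial spatial regression
areas: 100   chains: 2 x 6000 (burn 2500, thin 2)   seed: 42
random effects: iCAR + exchangeable
DIC: 1044.5  (Dbar 975.8, pD 68.7)   converged: True
                        mean       sd    2.5%      50%     97.5%    rhat significant
parameter
intercept            -4.8780   0.0905 -5.0400  -4.8830   -4.6970  1.0037        True
green_space          -0.7211   0.1661 -1.0751  -0.7139   -0.3931  1.0014        True
populous_grassroots   0.4147   0.0299  0.3525   0.4168    0.4732  1.0090        True
alpha                22.3243  29.8146  5.8214  13.0561  107.2941  1.0411         NaN
sigma_u2              0.4356   0.2219  0.1192   0.3873    0.9781  1.0449         NaN
sigma_v2              0.0491   0.0416  0.0056   0.0345    0.1532  1.0805         NaN
RR per +10 points of green space: 0.93
```

The generating truth here was `green_space = -0.5`,
`populous_grassroots = 0.44` and `sigma_u2 = 0.3`; every 95% credible
interval covers it, the positive Moran's I reflects the simulated iCAR
clustering, and the residual-risk surface is available as
`fit.residual_relative_risk()`.

The same pipeline is scriptable from the shell (`arealrisk simulate`,
`adjacency`, `exposure`, `greenspace`, `moran`, `screen`, `fit`, `report`);
`arealrisk report --bundle <dir>` runs screen → select → fit → compare and
writes the coefficient table, selection report and per-area risk surfaces.

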