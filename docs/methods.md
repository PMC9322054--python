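# Methods

This note documents the statistical model, the numerical choices behind the
sampler, what the synthetic-data generator does and does not emulate, and
the known limitations. It is the package's own account of its science;
empirical claims below are the ones the test suite and
`scripts/acceptance.py` actually compute.

## Model

Annual death counts `Y_i` in areas `i = 1..n` follow the BYM
(Besag–York–Mollié) negative-binomial regression

    Y_i ~ NB(mu_i, alpha),            Var(Y_i) = mu_i + mu_i^2 / alpha
    log mu_i = beta_0 + X_i beta + log population_i + u_i + v_i

with the NB2 parameterisation (`alpha` is the shape; Poisson is the
`alpha -> inf` limit). The offset fixes the population-rate interpretation.
`u` carries spatially structured risk through the intrinsic conditional
autoregressive (iCAR) prior on the contiguity lattice:

    u_i | u_-i ~ Normal( mean_{j ~ i} u_j , sigma_u^2 / n_i )

equivalently `p(u) ∝ exp(-(1/2 sigma_u^2) * sum_{i~j} (u_i - u_j)^2)`, an
improper density invariant to constant shifts per connected component; we
impose the usual sum-to-zero constraint per component and let the intercept
carry the level. Areas with no neighbours are excluded from the structured
term (`u_i ≡ 0`); their heterogeneity is carried entirely by the
exchangeable effect `v_i ~ Normal(0, sigma_v^2)`. Adjacency is queen
contiguity (any shared boundary point) by default — rook is available — and
island areas can be joined to the mainland with explicit extra links
(road/ferry connections) before fitting, which converts their singleton
components into ordinary lattice nodes.

Priors are deliberately vague and configurable: `beta_k ~ Normal(0, 1e6)`,
`sigma_u^2, sigma_v^2 ~ InverseGamma(0.01, 0.01)`,
`alpha ~ Gamma(0.01, 0.01)` (mean 1, variance 100).

## Inference

Inference is Metropolis-within-Gibbs MCMC:

- `beta` and `log alpha`: componentwise Gaussian random walks. Proposal
  scales adapt every 50 sweeps during burn-in toward 20–50% acceptance and
  are frozen afterwards, preserving detailed balance for the retained
  draws.
- `u`: single-site random-walk Metropolis, vectorised by graph colouring —
  areas of the same colour share no edge, so their single-site updates
  commute and can be evaluated as one numpy block per colour class
  (typically 4–6 classes for a queen grid).
- After each sweep `u` is re-centred to mean zero per connected component
  (the standard on-the-fly centring for the improper iCAR); the intercept
  absorbs the overall level through its own updates.
- `v`: all areas proposed at once; the components are conditionally
  independent, so elementwise accept/reject is exact.
- `sigma_u^2`: conjugate inverse-gamma draw from the pairwise-difference
  sum with shape `a + (n* - c)/2`, where `n*` counts areas with neighbours
  and `c` the non-singleton components (the Laplacian rank);
  `sigma_v^2` likewise from `sum v_i^2`.

Chains are initialised from the crude death rate (intercept) and a split of
the log standardised-ratio residuals (`u`, `v`), which places the sampler
near the posterior's bulk and avoids the startup trap where a near-zero
field makes the conjugate variance draw collapse. Seeding uses
`numpy.random.SeedSequence` spawning, so a fixed spec seed gives
bit-identical chains; every workflow sub-fit derives its own seed from the
master seed and its labels via SHA-256.

Convergence is summarised by the split-chain Gelman–Rubin statistic on the
monitored scalars (coefficients, `alpha`, variances) with the conventional
1.1 threshold. Defaults are 4 chains × 15,000 iterations (burn-in 5,000,
thin 5); the test suite runs reduced chains (typically 2 × 3,000–6,000 on
81–100 areas), sizes chosen as the smallest at which the posterior
summaries are stable. Chain length is a numerical-accuracy control, not a
tuning knob: truncated chains visibly underestimate credible-interval
width, which inflates the false-flag rate of significance screening (we
measured ~19% at 1 × 2,000 iterations vs ~4–8% at 2 × 5,000 against a 5%
nominal rate).

`nb_log_likelihood` switches to a `log1p`-based evaluation above
`alpha = 1e6` because the `gammaln(y + alpha) - gammaln(alpha)` difference
cancels catastrophically there; the stable branch reproduces the Poisson
limit to ~1e-6 at `alpha = 1e8`.

## Model selection and derived quantities

For each outcome the workflow fits one univariable model per candidate
covariate (intercept + offset + random effects + covariate), keeps those
whose 95% equal-tailed credible interval excludes 0, fits the joint model
on the kept set, and reports `DIC_multi - DIC_baseline` against the
covariate-free baseline. No multiple-testing correction is applied — a
faithful reproduction of common practice, and a documented caveat rather
than a silent fix. A failed univariable fit is logged and treated as "not
significant".

DIC uses the conditional focus: `D(theta) = -2 log L(y | beta, u, v,
alpha)`, `pD = Dbar - D(posterior means)`, `DIC = Dbar + pD`. Derived
surfaces: fitted `mu_i` (posterior mean), residual relative risk
`E[exp(u_i + v_i)]` (risk left over after covariates), and the per-area
posterior SD of `u_i + v_i` (or its exponential) as an uncertainty map.
Effect sizes convert as `RR = exp(coef * delta)` and percent change
`(1 - exp(coef * delta)) * 100`; green-space density enters as a fraction
in [0, 1], so a 10-percentage-point increase is `delta = 0.1`.

### A caveat on DIC and the NB-vs-Poisson structural comparison

`structural_comparisons` crosses {NB, Poisson} × {random effects on, off}.
Three orderings are sharp and reproduced in the tests: random effects
reduce DIC under either likelihood on clustered data, and NB crushes
Poisson when no random effect is present to absorb overdispersion. The
fourth comparison — NB + random effects vs Poisson + random effects — is
*not* reliably decided by conditional-focus DIC: a Poisson model with a
free per-area effect can interpolate gamma-type overdispersion through
`u`/`v` (we observe `sigma_u^2` inflating about 2.4× and the deviance at
the posterior mean reaching the Poisson saturated deviance), and because
the Poisson mass function is more peaked than any NB at the same mean, the
interpolating Poisson attains the lower DIC on data truly generated from
the NB model, across every overdispersion/count regime we scanned. This is
the documented failure mode of conditional DIC for comparing count
likelihoods in the presence of observation-level random effects (Millar,
*Biometrics* 65:962–969, 2009). The package reports the four DICs as
defined rather than substituting a different criterion; the corresponding
end-to-end recovery check in the acceptance suite fails by design of the
criterion, and we regard marginalised (integrated) model comparison as the
appropriate tool left for future work.

## Moran's I

`I = (n/S0) * z' W z / z'z` on centred values with row-standardised (or
binary) weights. The analytic null uses the randomisation moments
(`E[I] = -1/(n-1)`; the standard `S1/S2/b2` variance, defined for
`n >= 4`); the permutation null reports `p = (1 + #{I_perm >= I_obs}) /
(1 + n_perm)`, one-sided greater, resolution `1/(n_perm+1)`, default 999
permutations. Zero-neighbour areas are dropped with a warning. The Moran
scatterplot regresses the spatial lag on the centred value — the OLS slope
equals I under row-standardised weights (asserted to 1e-9) — and flags
influential areas by conventional single-case diagnostics (leverage
> 2(k+1)/n, |DFFITS| > 2√((k+1)/n), Cook's D > 4/n, |studentised residual|
> 2). Values exactly at the mean are labelled "Low" on both axes
(deterministic tie rule).

## Exposure assignment and green space

Stations above 200 m altitude or with more than 25% missing days are
excluded (strict inequalities: boundary values are retained), annual means
are taken over available days, and each area's centroid gets the nearest
surviving station by haversine distance on a 6,371-km sphere (planar
Euclidean available for projected inputs); exact distance ties break to
the lexicographically smallest station id. Green-space density is the
fraction of an area's land-use cells (cell-centre-in-polygon membership,
no-data cells excluded from numerator and denominator) whose class is
woodland, shrubland, grassland or wetland. At the 10 m grid resolution the
discrepancy between centre membership and area-weighted partial cells is
negligible.

## The synthetic-data generator

The generator emulates the structure of the motivating Hong Kong setting,
not its geography:

- **Lattice**: a `rows × cols` queen grid of rectangular cells plus
  `n_islands` detached offshore cells, default 14 × 14 + 5 ≈ 201 areas
  (the real study has 214 merged tertiary planning units, five of them
  neighbourless islands). Ferry links are suggested per island for the
  augmentation path.
- **Covariates**: a Gaussian copula matched to the published pairwise
  correlation table (five mutually orthogonal socioeconomic
  principal-component scores, ten exposure variables, e.g. min-temperature
  × NO₂ r = 0.39, green space × NO₂ r = −0.41), with margins rescaled to
  the published ranges (uniform within range; the copula preserves the
  rank structure, Pearson values land within ±0.05 of target). Green-space
  density is a fraction clipped to [0, 1]. The target matrix is repaired
  to the nearest positive-semidefinite correlation by eigenvalue clipping.
- **Counts**: drawn from the model itself — `u` from the exact
  constrained iCAR distribution (per-component Laplacian eigenbasis, so
  draws satisfy the sum-to-zero constraint to machine precision), `v`
  i.i.d. normal, NB sampling via the gamma–Poisson mixture.
- **Defaults** (chosen once, as the study conditions): true effects near
  the published multivariable magnitudes (green space −0.5 per unit
  fraction, populous grassroots +0.44 per score unit), baseline log-rate
  `beta_0 = −5.1` (≈0.6% crude annual mortality), `sigma_u^2 = 0.1`,
  `sigma_v^2 = 0.05`, `alpha = 10`, populations log-normal (median 2×10⁴,
  `sigma_log = 1`) mimicking dense-city heterogeneity.
- **Stations / land use**: 13 monitors with seasonal sinusoid + noise
  daily series and Bernoulli missingness (two monitors deliberately
  violate the altitude and missingness rules), and a smoothed random
  categorical land-use grid with ~2% water as no-data.

What the generator does **not** emulate: real boundary shapes and
adjacency irregularity, spatially structured exposure surfaces (covariates
are spatially unstructured across areas), measurement error in monitors,
and any temporal structure — the analysis is annual by design. Passing
recovery tests therefore demonstrate correctness of the machinery under
the model's own assumptions, not robustness to the misspecification real
data would bring.

## Verified behaviour (what the suite computes)

- Moran's I equals a double-loop oracle to 1e-9 on random lattices; the
  rook checkerboard attains exactly −1; permutation type-I error at
  nominal 5% is binomially consistent over 200 null simulations.
- The iCAR pairwise log-density equals the dense `u'(D−W)u` oracle to
  1e-9; sampled fields sum to zero per component to 1e-9; neighbour
  difference variances match the Laplacian pseudo-inverse closed form.
- NB log-likelihood matches an independent log-gamma oracle to 1e-9 and
  the Poisson limit at `alpha = 1e8` to 1e-5.
- Parameter recovery on 20 replicate synthetic studies (100 areas):
  per-coefficient 95%-interval coverage within [80%, 100%] and posterior
  means within 3 posterior SDs of truth in ≥95% of cells.
- Screening specificity on pure-noise covariates is binomially consistent
  with the nominal 5% rate (90 replicate×covariate cells).

## Limitations

- Conditional DIC cannot adjudicate NB vs Poisson once free per-area
  random effects are present (see above).
- `u` and `v` are individually weakly identified (only their sum enters
  the likelihood); variance partitioning between them should be read with
  care — a known property of the classical BYM parameterisation (scaled
  reparameterisations such as BYM2 address it and are out of scope here).
- The univariable screen inherits the usual perils of per-covariate
  selection with correlated covariates; the package reproduces the
  procedure, it does not endorse it.
- No spatial interpolation of exposures (nearest monitor only), no
  topology repair of invalid polygons, no spatiotemporal extension.
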