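# Methods

## Models

**Incidence.** For area `i` with observed count `y_i` and expected count
`e_i`, the BYM model is `y_i ~ Poisson(e_i θ_i)`, `log θ_i = α + u_i + v_i`.
The intercept `α` has a mean-zero normal prior with variance 1e10. The
spatial effect `u` carries an intrinsic CAR prior: joint density
proportional to `exp(−τ_u/2 · Σ_{i~j} (u_i − u_j)²)` on the sum-to-zero
subspace, equivalently each `u_i | u_{−i} ~ N(mean of neighbours,
1/(τ_u n_i))`. The heterogeneity `v_i ~ N(0, 1/τ_v)` is iid. Expected
counts come from indirect standardisation with the pooled dataset as its
own reference (18 five-year age groups by sex), so `Σ e_i = Σ y_i` per sex
and SIR = 1 is the regional average; an external reference-rate table can
be substituted upstream by supplying `e_i` directly.

**Relative survival.** Individual records are collapsed to cells indexed by
broad age group `k`, follow-up year `j = 1..5` and area `i`, holding exact
person-years `y_kji`, observed deaths `d_kji`, and expected background
deaths `d*_kji` accumulated from a population life table. The model is
`d_kji ~ Poisson(μ_kji)` with `log(μ_kji − d*_kji) = log y_kji + α_j + β_k +
u_i + v_i`; `μ > d*` holds for every admissible state by construction and
is asserted at each likelihood evaluation. All `α_j` are free (the excess
hazard varies by follow-up year); the first broad age group is the
reference with `β_1 = 0` to identify the intercepts. `α_j` and `β_k` have
mean-zero normal priors with variance 1e6. Cells without person-time carry
no information and break the offset, so they are dropped from the
likelihood. The mapped relative excess risk is `RER_i = exp(u_i + v_i)`.

**Hyperpriors.** Six presets per model mirror the sensitivity grid the
configuration is drawn from; the defaults are preset 3 in both cases:
incidence `τ_u ~ Gamma(0.1, 0.1)`, `τ_v ~ Gamma(0.001, 0.001)`; survival
`τ_u ~ Gamma(0.1, 0.01)`, `τ_v ~ Gamma(0.1, 0.01)`. Uniform-on-sigma
presets are supported via Metropolis updates on `log τ`.

## Data preparation

Survival exclusions drop, with one reason recorded per record: age at
diagnosis ≥ 90; death-certificate-only registrations; autopsy-only
registrations; survival time ≤ 0 days; and records contributing no at-risk
time inside the study window within five years of diagnosis. Survivors at
the window end are censored there. An exit date before diagnosis without a
death flag is treated as data corruption and rejected.

Person-time splitting is day-exact (person-years = days/365.25): each
record's at-risk interval is cut at annual anniversaries of diagnosis and
at the window boundaries. Expected background deaths use the life-table
rate at the record's attained age, sex and calendar year at each segment's
midpoint — an Ederer-II-style approximation appropriate for collapsed data
with annual life tables; day-level exactness in the rate lookup would be
spurious. Broad age groups default to {<60, 60–69, 70–79, 80+} by age at
diagnosis and are configurable.

## Sampler

A single chain of Metropolis-within-Gibbs sweeps in fixed order: intercept
block, `u` by graph colour class, sum-to-zero re-centring of `u` with the
shift absorbed into the intercept(s), `v`, then the precisions. Proper
graph colouring makes all areas within a class conditionally independent,
so single-site random-walk updates are applied to whole classes at once.
Proposal scales adapt by Robbins–Monro steps toward 44% acceptance during
burn-in and are frozen afterwards. Gamma-prior precisions use conjugate
Gibbs draws with the CAR quadratic form's rank equal to (areas − graph
components).

Vague Gamma hyperpriors induce a funnel between each precision and its
effect vector which single-site updates traverse slowly — on a three-area
test problem the seed-to-seed spread of posterior means exceeded the
nominal Monte-Carlo error. Each sweep therefore ends with two interweaving
scale moves: propose `τ → τ e^δ`, `x → x e^{−δ/2}` (keeping `x√τ` fixed),
for which the Gaussian prior and Jacobian cancel and the acceptance ratio
reduces to the likelihood ratio times `τ^a e^{−bτ}` evaluated at the two
precisions. Default schedules: burn-in 100,000 (incidence) / 250,000
(survival), then 100,000 iterations thinned 1-in-10 (10,000 stored draws);
a desk-scale schedule (5,000 / 5,000 / 5) serves simulation studies.
Summaries are posterior medians with central 95% credible intervals; all
percentiles use linear interpolation between order statistics (type 7).

## Diagnostics and sensitivity statistics

The Geweke statistic compares the mean of the first 1,000 kept draws with
the mean of the last 5,000, standardised by the spectral-density-at-zero
standard errors of the two windows (Yule-Walker AR fit, order by AIC);
areas with two-sided p < 0.01 are flagged. Trace/density/autocorrelation
tables are emitted for 5% of areas: half the sample taken from the areas
with the smallest counts, the rest a seeded random draw.

`pD` is the mean posterior deviance minus the deviance at the posterior
means of `(α, u, v)`, using the plain Poisson deviance `−2 log L`
(including the `log y!` term); `DIC` = mean deviance + `pD`. The spatial
fraction is the posterior mean of `sd(u)/(sd(u)+sd(v))` computed per draw
from the empirical spread of the two effect vectors; the 90% ratio is the
95th over the 5th percentile of the per-area posterior-median map. These
two are declared conventions: the source tables print them without
defining the estimator.

## Clustering test

Tango's MEET uses an exponential kernel `exp(−d_ij/λ)` on centroid
distances, a default grid of 10 log-spaced `λ` spanning the 1st–99th
percentile of pairwise distances, and multinomial Monte-Carlo calibration:
one replicate set estimates the per-λ null mean and variance, a second
independent set calibrates the minimised p-value, and the adjusted p uses
the add-one rule with `n_rep = 999` by default. Inputs are the modelled
observed values — median SIR × expected for incidence; per-area adjusted
deaths `Σ y e^{α_j} e^{β_k} RER_i + d*` with posterior-median parameters
for survival, against their RER = 1 companions. Evidence bands: p < 0.01
strong, < 0.05 moderate, < 0.10 weak, otherwise none; the category is
stabilised over six seeded runs, resolving disagreement to the less
significant category. Stratum aggregation instead evaluates the modelled
observed values per kept iteration, sums them within socioeconomic or
rurality strata, and divides by fixed expected totals (for survival,
computed at the posterior-median coefficients with RER = 1 — the package's
reading of an aggregation step whose original description is ambiguous on
this point).

## Geography

Queen contiguity: two areas are neighbours if their boundaries share any
point, edge or corner included; first-order only. Isolated areas (islands)
are repaired by user-supplied manual links first — the original analysis
grouped islands by expert judgement, which no automatic rule reproduces —
then any remaining isolate links to the area with the nearest centroid,
ties broken by area-id order. Coordinates are planar; users with geodesic
data should project upstream. The GAL dialect read and written is: header
line with the area count, then per area a line `id n` and a line of `n`
neighbour ids; asymmetric files are rejected.

## Synthetic data

The generator emulates registry inputs: a unit-square lattice with
detached island polygons; area populations log-normal around 8,000 persons
(the scale of a state of ~4 million split into ~500 areas) across 18
five-year age groups, two sexes and the study years, with a shared
age structure declining smoothly with age; a Gompertz-like life table
(rates doubling roughly every 8 years, slightly higher for males, constant
over calendar time); Poisson incidence counts driven by
`α + u_i + v_i` with `u` drawn by Gibbs sweeps from the CAR conditionals,
centred and rescaled to a requested empirical standard deviation (the
exact intrinsic CAR field is improper, so its marginal scale is defined
empirically); and survival records whose total hazard in follow-up year
`j` is the life-table rate plus `exp(α_j + β_k + u_i + v_i)`, with event
times drawn piecewise-exponentially at yearly resolution and censoring at
the window end. Default study conditions used by the validation studies:
10×10 incidence lattices with 50 expected cases per area, `σ_u = 0.3`,
`σ_v = 0.1`; 8×8 survival lattices with 20,000 cases and yearly excess
hazards 0.30/0.20/0.12/0.08/0.06 with age effects (0, 0.3, 0.6, 1.0).

What the generator does **not** emulate: age-structure differences between
areas, calendar-time trends in rates, cause-of-death misclassification,
registry late-registration artefacts, or irregular real-world geographies.
Passing recovery tests therefore demonstrate that the estimators recover
the model they assume at realistic sizes — not robustness to model
misspecification in real registry data. The survival generator matches the
fitting model's piecewise-exponential assumption deliberately, so
parameter-recovery tests isolate the sampler from model error.

## Validation oracle

For graphs of up to three areas the posterior is integrated numerically as
an MCMC-free reference. A first implementation — one Laplace-whitened
tensor grid over the density with the precisions marginalised analytically
— was biased: the near-flat `Gamma(0.001, 0.001)` hyperprior makes the
effect marginal spike-plus-slab, which no single whitened grid resolves.
The shipped oracle instead grids `(log τ_u, log τ_v)` on a regular mesh
(step 0.5 over [−16, 12], where the profile is smooth), and for each
precision pair integrates the conditional — a log-concave Poisson GLM with
Gaussian priors — by Gauss-Hermite quadrature centred at the conditional
mode (damped Newton) and scaled by the conditional Hessian, after a
Laplace screening pass discards precision pairs more than 20 nats below
the maximum. The result is stable to ~2×10⁻⁴ under node-count and
step-size refinement and was cross-checked against an independent
affine-invariant ensemble sampler.

For the survival model the oracle comparison uses the centred log relative
excess risk, `(u_i + v_i) − mean_j(u_j + v_j)`, rather than `exp(u_i +
v_i)` itself: the excess-mortality likelihood is invariant to shifting all
intercepts up and all area effects down, that direction is pinned only by
the vague intercept priors, and the resulting posterior mean of the
un-centred `exp(u_i + v_i)` is dominated by astronomically improbable
prior-tail states no finite sampler can visit. The centred contrasts are
shift-invariant and well posed; posterior-median RER reporting (what the
maps use) is unaffected because medians are quantile-robust and the
pathology vanishes once many areas identify the precisions.

## Problem sizes and numerical choices

Validation studies run at: three areas with a production-scale chain
(200,000 iterations) for the oracle comparison; 10×10 lattices with the
desk-scale schedule for recovery and null calibration; 200 null datasets
with 500 replicates each for the clustering test's type-I error; 8×8
lattices with 20,000 simulated cases for survival recovery; 478 chains of
10,000 draws for Geweke calibration. These sizes give each study enough
resolution for its acceptance band while keeping the full suite
comfortably reproducible on a single CPU.

Other numerical choices: the sum-to-zero constraint is enforced by
re-centring each sweep (tolerance 1e-6 in the density evaluation);
deterministic seeding throughout with one generator per fit and a fixed
update order; zero-variance chains define a Geweke z of 0; the boundary
p-value of the clustering test is `(1 + #{replicates ≤ observed})/(1 +
n_rep)`; map classes are `(0, 1/1.3), [1/1.3, 1/1.1), [1/1.1, 1.1],
(1.1, 1.3], (1.3, ∞)` — the central class closed on both sides, a
convention the cut-off definition leaves open.

## Known limitations

Single-chain inference only (by design); no between-chain diagnostics.
No covariate-adjusted incidence models, no period/hybrid survival
estimation, no local cluster detection, and no cartographic styling —
exports are category-labelled GeoJSON and CSV tables. The quadrature
oracle requires Gamma precision priors and at most a handful of areas.
Uniform-on-sigma hyperprior presets are sampled by Metropolis steps and
mix more slowly than the Gamma presets' conjugate updates.
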