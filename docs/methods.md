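# Methods

`healthcast` implements a chain of estimators for country-level health
financing futures and their link to universal health coverage (UHC). This
note records the models, their assumptions, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data tests do and do
not establish.

## 1. Data model

The unit of analysis is the country-year. A panel carries GDP per capita,
total government spending, the four mutually exclusive health-spending
sources (government = GHES, prepaid private = PPP, out-of-pocket = OOP,
development assistance = DAH, all per capita), population, a UHC
service-coverage index on 0–100, and fixed income-group and super-region
labels. All currency is taken as 2017 PPP-adjusted dollars; the package
performs no deflation or currency conversion — adjustment is upstream of
ingestion. Countries with gaps in their year runs are rejected rather than
imputed, because every estimator in the chain assumes contiguous series.

Two derived aggregates recur throughout:

* **total** health spending per capita = GHES + PPP + OOP + DAH;
* **pooled** (prepaid, risk-pooled) resources per capita = GHES + PPP + DAH
  — out-of-pocket payments are excluded because they pool no risk.

## 2. Synthetic worlds

The generator (`synth`) emits panels with exactly the structure the
estimators assume, so that every stage can be validated by parameter
recovery. Defaults describe a world of 188 countries observed 1995–2015.

* **GDP.** `growth_t = mu_c + beta_convergence * log(gdp_pc)_{t-1} + eps`,
  with `beta_convergence = -0.01` (higher-income countries grow more
  slowly), country drifts centred on 2 %/year, and innovation sd 0.02 —
  magnitudes typical of cross-country growth panels.
* **Shares.** The four financing shares (government spending/GDP, health
  share of the government budget, prepaid private/GDP, out-of-pocket/GDP)
  follow AR(1) processes on the logit scale around country-level
  intercepts, so they live in (0, 1) without truncation. Centres are ~30 %,
  ~15 %, ~1 % and ~2 % respectively.
* **UHC frontier.** `uhc = clamp(exp(a + b log(pooled_pc) + v - u), 0, 100)`
  with `v ~ N(0, 0.03²)` and half-normal `u` with scale 0.25. The default
  slope is `b = ln(1.014)/ln(1.10) ≈ 0.1459`, i.e. a 10 % rise in pooled
  spending per capita carries a 1.4 % rise in the index.
* **DAH.** Per-capita receipts decline log-linearly with income and are
  zero above the World Bank high-income threshold of $13,741 GDP per
  capita. A flow network adds sources (state sources as a stable 0.05–0.2 %
  share of a donor's government spending; non-state sources as stationary
  AR(1) series) and recipient shares that sum to one each year.
* **Covariates.** The demographic covariates (population age fractions,
  education years, fertility) are AR(1) series around income-linked country
  means. They are deliberately simple: the generator reproduces the
  *statistical shape* the estimators assume, not the joint distribution of
  real demographic data.

A single seed fully determines the output. **What passing tests show:** the
estimators recover the parameters of data satisfying their own assumptions
at realistic sample sizes. **What they do not show:** robustness to the
things real panels add — measurement revisions, structural breaks, civil
conflict discontinuities, correlated shocks across countries, or share
dynamics that leave the logit-AR(1) family.

## 3. Ensemble spending projection

GDP growth and the four financing shares are projected with a model
ensemble rather than one regression. A grid of candidates crosses:

* covariate subsets from {fraction under 20, fraction over 65, education
  years, total fertility rate, convergence term}, where the convergence
  term is always the 1-year lag of the non-differenced dependent variable;
* four recency-weight profiles `w_t = exp(-λ (T - t))`,
  λ ∈ {0, 0.05, 0.1, 0.2} — λ unstated by any source, chosen to span
  "no weighting" to "recent decade dominates", and configurable;
* AR and MA orders 0–3 for the residual process.

Targets are fitted on the growth scale: log-difference for GDP per capita,
logit-difference for the shares (so back-transformed paths stay in (0, 1)).
The default grid (all 16 demographic subsets, each with the convergence
term, × 4 × 4 × 4 = 1024 specs per target) is configuration-driven; no grid
size is hard-coded.

**Estimation.** The mean model is weighted least squares, pooled across
countries, with two-sided t-test p-values. AR/MA residual structure is
fitted afterwards by conditional sum of squares on the within-country
residual series (the innovations filter restarts at country boundaries).
This two-stage split keeps the custom weight schemes exact in the mean
model and makes a 1000-model grid tractable on one CPU.

**Screening.** Candidates are dropped, in order, for (1) any covariate with
p > 0.10, (2) a positive convergence coefficient, (3) mean forecasts
outside the bounds of the target's historical growth. Each dropped model
records the first rule it violates; an empty retained set falls back to an
intercept-plus-convergence model with a warning rather than failing.

**Ranking and pooling.** Out-of-sample RMSE comes from refitting with the
last 5 observed years held out and scoring one-step predictions on the
holdout. Retained models receive weight ∝ 1/RMSE²; Monte-Carlo draws
(default ≥ 1000) are allocated by largest-remainder rounding, and each
model contributes forecasts under coefficient vectors sampled from its
asymptotic posterior N(coef, cov). Per-model substreams and output order
are keyed by a stable hash of the specification, so the pooled distribution
is invariant to permutation of the retained list.

**Forecast mechanics.** Demographic covariates are held at their last
observed values (trend modelling of covariates is out of scope); the
convergence term updates dynamically with the projected level; the ARMA
residual forecast decays from the last observed residuals.

**Noise.** Empirical noise is added as a first-order random walk on the
*level* path: independent N(0, sd_c²) increments per forecast year on the
growth scale, which the chaining step cumulates, giving level-noise
variance h·sd_c² at horizon h. sd_c is the country's holdout residual sd,
so countries the sub-models fit poorly get the widest intervals. (Adding
*cumulated* noise to the growth increments instead would compound twice and
inflate level variance like h³ — `add_random_walk_noise(cumulative=...)`
makes the scale explicit.)

**Chaining.** Projections are sequenced so identities hold within every
draw: government spending = share × GDP; GHES = share × government
spending; OOP and PPP = share × GDP; total = sum of components, with DAH
added by the next stage. Population is projected by log-linear continuation
per country.

## 4. DAH projection

State sources provide `share_of_gov × government spending` per draw, so
their futures inherit the government-spending projection. Non-state sources
are forecast by ARIMA with no covariates; the order is selected by AIC over
p, q ≤ 2, d ≤ 1 (no order is canonical for such series), with a (0,1,0)
random-walk fallback on fit failure. Totals are allocated to recipients by
annual shares (held at the last observed year going forward), which must
sum to one to within 1e-9.

The income transition is evaluated *within each draw* on that draw's GDP
path: DAH is zeroed from the first year GDP per capita exceeds $13,741,
absorbing thereafter (no re-entry). Freed amounts are redistributed
proportionally over the remaining eligible recipients, preserving
conservation over the eligible set. Note a consequence: with redistribution
on, raising the threshold can *lower* an always-eligible recipient's DAH
(it loses redistributed amounts); the per-recipient monotonicity property
holds exactly with `renormalize=False`, and the tests check it there.

## 5. Better and worse scenarios

The 20-year annualised log growth of total health spending per capita,
`(log x_end − log x_start)/span`, is regressed across countries on the
window-start log level (the convergence term at the start of the window).
Better and worse growth rates add the 85th and 15th percentiles of the
residuals to each country's fitted value; paths grow from the last observed
level at those constant rates. Quantiles interpolate linearly between order
statistics ("type 7") — the convention matters at n = 188 and is
configurable. Scenarios are clipped elementwise to bracket the reference
(better := max(better, reference), worse := min(worse, reference); the
operation is idempotent), then propagated to components — including DAH —
by proportional scaling, so component sums equal scenario totals exactly.

## 6. UHC frontier

The frontier is log-log: `log(uhc) = alpha + beta log(pooled_pc) + v − u`
with half-normal inefficiency. The log link (rather than logit) is the
default because the association is naturally stated as "% per 10 %"; a
clamp at 100 caps predictions. Parameters are estimated by maximum
likelihood (L-BFGS-B on (alpha, beta, log σ_v, log σ_u)), started from
corrected OLS — the residual skewness supplies the initial inefficiency
scale — with a second near-zero-inefficiency start to guard against
wrong-skew samples. As σ_u → 0 the estimate collapses to OLS, which the
tests verify to 1e-3 on n = 2000. All country-years 1995–2015 enter one
pooled fit with no country effects: the envelope is set by the full range
of peer countries.

Per-observation inefficiency uses the conditional mean E[u | v − u]
(the Jondrow–Lovell–Materov–Schmidt estimator), which is non-negative by
construction. Gap trajectories regress each country's log gap on year with
precision-weighted shrinkage of the slope toward the global mean slope
(between-country slope variance by method of moments, floored at zero);
projection on the log scale keeps gaps non-negative. Countries with fewer
than 5 gap observations hold their last gap constant, with a warning. Gaps
are floored at 1e-6 before taking logs.

Scenario UHC is `clamp(frontier(pooled) × exp(−gap), 0, 100)`; with a
common gap, the spending ordering of scenarios carries over to coverage.
Frontier parameter uncertainty can be propagated per draw by sampling
(alpha, beta) from the MLE's asymptotic covariance (numerical Hessian); the
fast preset uses a single fit.

## 7. Aggregation, decomposition, uncertainty

Lives covered treats the index as a coverage proportion:
`(uhc/100) × population`, summable across countries and never exceeding
population. Group aggregates use totals ratios for per-capita spending and
population weights for the index.

The change in coverage decomposes via the two-factor Das Gupta identity.
Writing UHC = F × E with F the frontier value at the country's pooled
spending and E = UHC/F the efficiency multiplier:

    spending effect   = (E₀ + E₁)/2 × (F₁ − F₀)
    efficiency effect = (F₀ + F₁)/2 × (E₁ − E₀)

The effects sum to the total change exactly and the formula is symmetric in
factor order. Default periods are 2015→2030 and 2030→2040.

Summaries report the draw mean and the 2.5th–97.5th percentile interval
(type-7 quantiles) per cell; the default draw count is 1000.

## 8. Pipeline and determinism

Stages run in order simulate → ensemble → DAH → scenarios → frontier →
report, each writing CSV artifacts headed by a `#` metadata block (stage
name + config hash). A single root seed drives everything; per-stage
substreams hash the stage name with the seed, so adding a stage never
shifts another's randomness, and two runs with the same config are
bit-identical. A stage is skipped on resumption when its artifacts exist
with a matching hash and nothing upstream was recomputed. The output
directory is excluded from the config hash (a storage location, not a
modelling choice).

Two presets exist: `fast` (20 countries, 100 draws, compact grid, single
frontier fit) for development and smoke checks, and `full_fidelity`
(188 countries, ≥1000 draws, per-draw frontier sampling). Tests and the
reproduction script use sizes chosen to make Monte-Carlo tolerances tight
while keeping single-CPU runs short: e.g. 25 replicates of the 188 × 21
frontier recovery, 1000 replicates of the p-value screen calibration at
6 × 12, and 100,000 draws for the random-walk variance check.

## 9. Known limitations

* Covariate futures are last-value continuations, not modelled trends.
* The frontier is static (no year effects or time-varying frontier); a
  config hook exists but the default and all validation use the static fit.
* The DAH recipient-share model holds last observed shares constant rather
  than modelling share dynamics.
* No financial-risk-protection dimension of UHC is modelled; the index is
  service coverage only.
* The grid's two-stage estimation (WLS mean model, then CSS-ARMA residuals)
  is not full joint maximum likelihood; for the short series involved the
  difference is dominated by model-selection uncertainty, which the
  ensemble itself carries.
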