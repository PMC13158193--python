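# Methods

This note records the models, conventions and design choices behind
`nprescribe`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Pipeline

1. **Data.** A field table (CSV, one row per site/season sample) with a
   continuous yield target, an applied nitrogen rate N (kg/ha), and
   covariates in four groups: weather/climate, soil/terrain, crop-condition
   indices (NDVI, EVI, LAI, chlorophyll) and management/categorical
   identifiers including region, crop type, season, year and
   planting/harvest dates.
2. **Deduplication** by exact row match after type normalization (trimmed,
   lowercased categoricals; ISO dates).
3. **Grouped split.** Canonical key `region||crop||year||season` (trimmed,
   lowercased, missing → `unknown`, year as a base-10 integer string);
   group id = SHA-256 of the UTF-8 key. Unique ids are sorted, shuffled with
   a fixed seed (default 42), and assigned greedily against row-count
   targets 60/20/20 in the order train → calibration → test. All rows of a
   group land in one partition; the assignment is invariant to input row
   order and identical across platforms.
4. **Preprocessing**, fit on train only: median imputation for numerics,
   reserved `unknown` category for missing/unseen categoricals,
   quantile winsorization, one-hot encoding, standardization
   z′ = (z − μ_tr)/(σ_tr + ε) with ε = 1e−8.
5. **Model selection.** Ridge, an additive spline model, and a
   random-forest ensemble are fit on train and compared by calibration-split
   RMSE; lowest wins, ties break toward the simpler family.
6. **Split conformal calibration** of absolute residuals at each coverage
   level (defaults 0.90 and 0.95).
7. **Decision layer.** For each test sample the model is swept over the
   candidate grid (10–200 kg/ha, step 5); yield intervals propagate to
   profit intervals; the LCB, expected-profit, uniform and point-EONR rules
   produce prescriptions; the abstention policy filters the LCB rule.
8. **Reports**: decision metrics, group-wise paired differences,
   coverage/abstention trade-off with binned abstention maps, feature-group
   ablations, and economic scenario sensitivity.

## Conventions and numerical choices

- **Winsor quantiles** default to (0.01, 0.99); bounds are empirical
  quantiles with linear interpolation of order statistics. Mild clipping
  limits extreme-value influence while preserving rank order. Yield and N
  are winsorized like other numerics, but yield is never standardized (it
  stays in native units for the profit model) and grid-override rates are
  standardized without winsorization (they are decision inputs, not noisy
  measurements).
- **Standard deviations** use the population convention (divide by n),
  both in preprocessing and in all dispersion reports.
- **Conformal quantile**: exact order statistic r = ⌈(n+1)(1−α)⌉, no
  interpolation — interpolation would forfeit the finite-sample guarantee.
  If r > n (tiny calibration sets) the maximum score is used, a
  conservative documented fallback.
- **Additive family**: cubic B-splines per continuous feature, 5 interior
  knots at training quantiles {1/6,…,5/6}, one-hot columns entering
  linearly, no interactions, single ridge fit with penalty η = 1.0.
  Degenerate (near-constant) features fall back to uniformly spaced knots.
- **Tree ensemble**: bagged random-forest regressor, 300 trees, fixed seed.
  Chosen as a robust default for heterogeneous tabular response; the family
  is swappable via `ModelConfig`.
- **Quantile-regression comparator**: gradient-boosted pinball regressors
  per quantile, crossing repaired by sorting endpoints. **Ensemble
  comparator**: M = 10 bootstrap refits of the selected main family,
  central percentile interval. **Dropout comparator**: an in-package
  2×64-unit ReLU network with inverted dropout (p = 0.20) kept active at
  prediction time, T = 50 stochastic passes, percentile interval; trained
  with Adam on standardized targets for a fixed epoch budget.
- **Ties** in every grid argmax break toward the smallest rate —
  deterministic and environmentally conservative.
- **Economic defaults** p_g = 1.0, c_N = 0.02, c_app = 0.25, λ = 0.5 are
  artifact defaults on an abstract currency/yield scale, chosen so that
  profits land in the low single digits on the generator's yield scale;
  every value is configurable. The global reference-rate fallback is
  105.19 kg/ha.

## The synthetic generator

The generator emulates the statistical structure the framework assumes, not
any particular real dataset. Yield follows a group-specific concave
quadratic, y = a(r,c) + Δa(x) + (b(r,c) + Δb(x))·N − c(r,c)·N² + ε, with
per-(region, crop) coefficients drawn once per seed (a ∈ [2, 4] yield
units, b ∈ [0.025, 0.05] per kg/ha, c ∈ [8e−5, 2e−4] per (kg/ha)²) and
small linear loadings Δa, Δb on standardized covariates (NDVI, organic
carbon, rainfall, slope, water-holding capacity) so that contextual
features carry signal. Noise is Gaussian with sd 0.6 × (1 + |z_rain|/2)
when heteroscedastic noise is enabled, concentrating wide intervals in
extreme-rainfall regimes. Sand/silt/clay fractions are Dirichlet draws
scaled to sum to 100; planting/harvest dates are synthesized per season
with jitter so season-timing features are derivable; covariate cells (never
yield or N) go missing independently at a configurable rate (default 2%);
duplicated records can be injected for deduplication testing (default off).

What the generator does *not* emulate: real spatial autocorrelation,
measurement error structure in remote-sensing indices, non-quadratic
(e.g. plateau) response shapes, or temporal carry-over between seasons.
Passing tests on this generator therefore demonstrate the correctness and
calibration of the machinery under its stated assumptions, not field-level
validity of any particular prescription.

The quadratic family is deliberate: it admits the closed-form optimum
(p_g·b − c_N)/(2·p_g·c), giving an oracle for testing grid optimization,
and its realized profit can be evaluated noise-free at counterfactual rates
(`oracle` evaluation mode). For real data the `model_estimate` mode uses
the fitted model's own prediction at the prescribed rate; the mode is
stamped on every report because counterfactual profit on observational data
is an assumption, not a measurement.

## Structural properties worth knowing

- **LCB equals expected-profit pointwise under split conformal.** The
  conformal interval has constant width 2q, so the profit lower bound is
  L_π(N) = π̂(N) − p_g·q — a constant downward shift. The LCB and
  expected-profit argmaxes therefore coincide sample-by-sample, and the
  dispersion comparison between the two rules is evaluated with abstention
  disabled (where it holds with equality). Differences between the rules
  emerge only through the abstention filter, or with interval methods whose
  width varies with N.
- **Abstention is monotone in the coverage level.** Raising the level
  enlarges q, which widens every profit interval, enlarges the ambiguity
  set and can only add abstention triggers; the per-sample abstention
  indicator is non-decreasing from 0.90 to 0.95.
- **The ambiguity threshold.** Profit along the candidate grid is flat near
  the optimum (with curvature c ~ 1e−4, profit changes by ~0.03 currency
  over 15 kg/ha) while conformal profit intervals are ~2–4 currency units
  wide, so the ambiguity set typically spans 85–100 kg/ha. The default
  threshold is therefore half the default grid span (95 kg/ha): abstain
  when the economically indistinguishable set covers more than half of the
  candidate range. A tighter agronomic threshold (e.g. 30 kg/ha) abstains
  on essentially every sample under this construction.
- **Coverage on the grouped split** can fall slightly below nominal:
  assigning whole region×crop×year×season groups to partitions breaks
  exchangeability between calibration and test (that is the point of the
  split — it emulates deployment to unseen contexts). The coverage
  *guarantee* is measured under an exchangeable row-level split
  (`coverage_simulation`), where it holds at or above nominal up to
  binomial noise.
- **Reference rates for `unknown` subgroups.** Rows whose region or crop
  labels are missing form `unknown` subgroups; their training-mean
  reference rates can be noisy when the subgroup is small, which feeds
  directly into the surplus penalty. This is the literal consequence of the
  reference-rate definition and is left as such.

## Problem sizes

Default experiment sizes in the tests and the acceptance script were chosen
as the package's own desk-scale study conditions: the coverage simulation
uses 4000/1000/1000 train/calibration/test rows (binomial 3σ at n = 1000 is
±0.028 at the 0.90 level); decision-layer checks run on pipelines of
1200–2000 rows; the dispersion comparison repeats over five generator
seeds. All randomness flows from explicit integer seeds.

## Known limitations

- No conformalized quantile regression or group-conditional (Mondrian)
  calibration; the intervals are marginal.
- No continuous-rate optimization; prescriptions live on the grid.
- No mechanistic nitrogen-loss model; the environmental penalty is exactly
  the surplus proxy.
- The scenario engine perturbs economic parameters only; it never refits
  models or recomputes conformal quantiles (by design, to isolate economic
  sensitivity).
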