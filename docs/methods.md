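# Methods

## Cohort model and conventions

One record per insect: whole-day durations for each preadult stage reached,
sex (determined only at adult emergence; preadult deaths are recorded as
`undetermined`), the fatal stage, adult longevity in days, and a per-day
egg count for females. Age 0 is the day the egg was laid; the census is
strictly daily. Stage occupancy uses half-open day intervals: an individual
with a 3-day egg stage is an egg on ages 0–2 and a larva on age 3. For the
stage in which an individual died, the stored duration is the number of
days it survived there, so lifespans are exact person-day counts. The stage
ladder is fixed at egg → larva → pupa → adult; larval instars are not
resolved. Fecundity is credited to the mother's age-day of laying, not to
the offspring's age. Total pre-oviposition period (TPOP) is measured from
age 0 (egg deposition), which is why TPOP exceeds APOP plus the adult
emergence age by construction.

CSV I/O is deliberately strict: missing values are empty fields, explicit
`NA`-style tokens are rejected, and `read(write(c)) == c` holds field-exact
for every valid cohort.

## Life-table engine

- **Euler–Lotka root.** The residual Σ e^(−r(x+1)) lₓmₓ − 1 is strictly
  decreasing in r, so the solver bisects on [−1, 2] (widened automatically
  for pathological schedules) to ~1e−12 and polishes with a few Newton
  steps; the returned root satisfies the equation to < 1e−10. The (x+1)
  exponent convention (reproduction credited at the end of the day) is
  retained throughout, which makes T = ln R₀ / r and λ = eʳ exact
  identities of the output. The solver accepts an arbitrary — possibly
  fractional — age grid; the pipeline always passes integer ages, but the
  general grid makes single-age closed-form checks (r = ln R₀ / (a+1))
  exact.
- **Degenerate schedules.** R₀ = 0 leaves r, λ, T undefined and flagged.
  R₀ = 1 exactly gives r = 0 and T reported as the mean age of maternity
  Σ (x+1) lₓmₓ / R₀, the analytic limit of ln R₀ / r under this exponent
  convention, flagged in the output notes.
- **eₓⱼ and vₓⱼ.** Both use the hypothetical-cohort construction: daily
  transition frequencies between (age, stage) cells are tallied from the
  records, a pseudo-cohort is placed with probability 1 at (x, j), and
  pushed forward. eₓⱼ counts its expected person-days including the current
  day (so eₓⱼ ≥ 1 on occupied cells, and e₀,egg equals the cohort mean
  lifespan exactly). vₓⱼ accumulates e^(r(x+1)) Σᵢ e^(−r(i+1)) sᵢ,female
  f′ᵢ, where f′ is the per-capita daily fecundity of living females; male
  reproductive value is identically zero because males sire no offspring in
  this bookkeeping. Note that eₓⱼ need **not** decline monotonically with
  age within a stage for finite cohorts: the empirical hazard fluctuates,
  and once early-dying adults are gone the survivors' expectancy can rise —
  the familiar life-expectancy-at-age effect, not a bug.
- Cells never occupied by any individual are NaN, never silently zero.

## Bootstrap

The resampling unit is the individual: a replicate draws n individuals with
replacement, keeping each history intact, and recomputes every parameter.
This unit choice is validated by the binomial closed forms — with n = 20
and 19 survivors the bootstrap SE of Sa converges to √(0.95·0.05/20) ≈
0.0487, and with 9 females the SD of Fn to √(20·0.45·0.55) ≈ 2.22. The SE
is the SD of the bootstrap distribution (ddof = 1); 95% percentile
intervals are reported alongside. Replicates with no reproducing female
keep R₀ = 0 but contribute nothing to r, λ or T; the count of valid
replicates per parameter is reported. The default B = 100,000; the test
suite uses B = 2,000–10,000 with Monte-Carlo tolerances scaled accordingly.

Implementation: per-individual per-age egg and alive matrices are built
once, replicate schedules are row-sums over a single seeded index matrix,
and the Euler–Lotka root is found by a bisection vectorised across
replicates — bit-identical to the scalar engine (asserted in the tests)
and fast enough that B = 100,000 on an n = 20 cohort takes seconds.

For two-cohort contrasts, equal-sized cohorts share one index stream per
replicate (a paired bootstrap; comparing a cohort with itself gives exactly
zero differences), while unequal sizes fall back to independent streams
derived from the seed.

## Synthetic cohort generator

The generator's defaults are the study conditions of the four MSN doses;
they are calibration targets, not tuning knobs.

- **Stage durations**: gamma-distributed (positive skew typical of
  development times), CV 0.15, rounded up with a floor of one day. The
  continuous mean is pre-calibrated on the daily lattice so the discrete
  expectation equals the target exactly (naive ceiling adds ~half a day).
- **Mortality**: Bernoulli per stage, death day uniform within the fatal
  stage. Egg survival defaults to 1 (bioassays start with newly hatched
  larvae). Pupal survival is held at 0.95 and the remaining mortality is
  assigned to the larval stage — where leaf-mining exposure to treated
  foliage is concentrated — so the per-stage split is (1, Sa/0.95, 0.95).
- **Sex**: Bernoulli among emergers with p_female set to
  (cohort female-fraction target)/Sa, so that the expected female fraction
  of the whole cohort matches the tabulated Nf/N (0.45, 0.35, 0.20, 0.15)
  and Sa simultaneously.
- **Fecundity**: APOP ~ rounded gamma (CV 0.3); laying spread over a
  gamma-length window of consecutive days (CV 0.25) with an early-peaked
  triangular daily weight; daily counts Poisson with means scaled so the
  expected total equals the F target exactly. Adult longevity (gamma, CV
  0.2) is extended when needed so the drawn window fits, which slightly
  favours long-lived reproducing females at high doses.

What the generator does **not** emulate: temperature dependence, larval
instars, density effects, egg-viability differences, within-female
day-to-day autocorrelation of laying, or any mechanistic toxicokinetics —
dose acts only through the calibrated parameter sets. Passing tests
therefore show that the estimators recover known parameters under the
reported dose-response structure, not that the biology of any particular
rearing is captured.

Endpoint tables (plant SOD/POD/CAT/MDA, insect digestive and detox
enzymes) are Normal(mean, SD) truncated at zero, three replicates per
treatment, with hormetic profiles (peak at 30 mg L⁻¹, collapse at
300 mg L⁻¹) where the source reports them. Means not printed at full
precision (POD and MDA at 3 mg L⁻¹; most insect enzymes) are synthetic
stand-ins consistent with the described shapes, marked as such in the
module.

## Group statistics

Screen (Shapiro–Wilk on residuals, median-centred Levene, α = 0.05) →
transform only on failure (ln(x+1) for measurements, arcsine-√ for
proportions) → re-screen → one-way ANOVA + Tukey HSD if the screen passes,
otherwise Kruskal–Wallis + Dunn's z-tests with Holm adjustment.
Shapiro–Wilk runs on pooled residuals because per-group tests are
powerless at n = 3. Constant data make the screen non-assessable and route
to the nonparametric branch, where an all-tied sample is reported as
omnibus p = 1. Letters use the insert-and-absorb compact-letter-display
algorithm with alphabetical tie-breaking. Dunn's test is implemented
directly (mean-rank z statistics with tie correction) with Holm via
statsmodels. The full procedure's Type-I error under the null (4 groups,
n = 3, equal normal means) is calibrated at ≈ 0.05 and asserted over 2,000
simulations in the test suite.

## Correlation

Pearson coefficients over treatment-wise mean vectors (raw means by
default; transforms selectable upstream). With only 4 treatments these are
exploratory — no p-values or significance stars are attached, deliberately,
and the per-pair n is carried in the matrix metadata. Zero-variance
variables yield flagged NaN entries rather than silent zeros. The heatmap
clips its diverging colour scale to exactly [−1, 1] regardless of the data
range.

## Pipeline determinism

One master seed; each stage (and each treatment within a stage) derives
its own seed through `SeedSequence([master, stage_id, index])`, truncated
below 2³¹. The manifest records every output with a SHA-256 checksum;
identical configurations reproduce identical checksums, including the
rendered PNG.

## Problem sizes in the tests

Calibration and recovery checks use n = 2,000–10,000 simulated individuals
(recovery at 3 Monte-Carlo σ), dose-ordering of r uses n = 2,000 per dose,
bootstrap oracle checks use B = 2,000–10,000, and the Type-I calibration
uses 2,000 simulated endpoint tables — sizes chosen so each check is
decisively powered while the whole suite stays desk-scale.

## Known limitations

- Ages are whole days; sub-daily census data are out of scope.
- The engine reports cohort parameters only — no stable-age-distribution
  projection or forecasting.
- eₓⱼ/vₓⱼ assume the empirical daily transitions are Markov; with very
  small cohorts individual heterogeneity makes these matrices noisy.
- The paired bootstrap contrast reports percentile CIs, not hypothesis
  tests.
- Offspring are counts; egg viability of the next generation is not
  tracked.
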