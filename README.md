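# twosexlt

Age-stage, two-sex life tables for daily-census insect cohorts, with an
individual-resampling bootstrap for standard errors, dose-group statistics
and treatment-mean correlation analysis.

The package was built around a sublethal-toxicology study design: cohorts of
the tomato leafminer *Tuta absoluta* reared on tomato foliage sprayed with
mesoporous silica nanoparticles (MSN) at 0, 3, 30 and 300 mg L⁻¹, followed
individually every 24 h from egg to death. It is equally usable for any
insect cohort censused daily through an egg → larva → pupa → adult ladder.

## The model

Each of *n* newborns is tracked through stages *j* (egg, larva, pupa,
female adult, male adult). From the individual records the engine computes:

- **sₓⱼ** — fraction of the initial cohort alive and in stage *j* at age
  *x* (ages in days, age 0 = day the egg was laid);
- **lₓ = Σⱼ sₓⱼ** and **mₓ = Σⱼ sₓⱼ fₓⱼ / Σⱼ sₓⱼ**, where fₓⱼ is nonzero
  only for female adults (eggs per living female per day);
- **R₀ = Σ lₓmₓ**, **GRR = Σ mₓ**;
- **r** solving the discrete Euler–Lotka equation
  Σₓ e^(−r(x+1)) lₓmₓ = 1, with **λ = eʳ** and **T = ln R₀ / r**;
- **eₓⱼ** (life expectancy) and **vₓⱼ** (reproductive value) via the
  hypothetical-cohort construction: a pseudo-cohort placed with certainty
  at (x, j) is pushed forward with the empirically observed daily
  stage-transition and survival frequencies;
- reproduction summaries: Fn, RepF, male count, APOP, TPOP, preadult
  survivorship Sa, oviposition days, eggs per female F, female fraction.

Standard errors come from resampling whole individuals with replacement
(default B = 100,000 replicates) and recomputing every parameter per
replicate; replicates where a parameter is undefined (no reproducing
female) are excluded and counted.

A calibrated generator (`twosexlt.simulate`) emits synthetic cohorts whose
expectations match the four dose groups (e.g. Sa falling 0.95 → 0.40,
larval duration stretching 7.4 → 11.8 d, fecundity dropping 208.22 → 47.33
eggs per female, cohort female fraction 0.45 → 0.15), so the entire
pipeline runs without any external data.

## Worked example

```python
from twosexlt import TwoSexLifeTable, simulate

params = simulate.default_params("0")          # untreated control, n = 20
cohort = simulate.simulate_cohort(params, seed=7)
res = TwoSexLifeTable(cohort).fit(bootstrap_reps=2000, seed=7)
print(res.summary())
```

```
Age-stage two-sex life table results
  treatment: 0    n = 20    census: daily
  e_xj / v_xj method: hypothetical-cohort (Chi & Su 2006 convention)
  bootstrap: B = 2000 (individual resampling), seed = 7
  parameter           estimate     boot SE      ci low     ci high
  r                     0.2259      0.0112      0.2004      0.2435
  lambda                1.2534      0.0140      1.2219      1.2757
  R0                  125.1500     22.7681     78.6975    167.2012
  ...
  Sa                    0.9500      0.0491      0.8500      1.0000
  F                   208.5833      4.4328    199.3000    217.2267
```

Read: this simulated control cohort grows at r ≈ 0.23 d⁻¹ (λ ≈ 1.25-fold
per day), each newborn contributes R₀ ≈ 125 offspring on average (this
seed happened to draw 12 females out of 20; the expectation is 9), 95% of
the cohort reached adulthood (Sa), and females laid ≈ 209 eggs each (F).
The bootstrap SE column is the SD of each parameter across 2,000
individual resamples.

The same flow is available from a shell:

```bash
twosexlt simulate -t 0 --seed 7 --out cohort0.csv
twosexlt lifetable --cohort cohort0.csv --fecundity cohort0_fecundity.csv
twosexlt run --seed 1 --out results/run1 -B 10000   # full pipeline + manifest
```

## Layout

- `twosexlt.cohort` — individual records, cohort tables, CSV round-trip
- `twosexlt.simulate` — calibrated synthetic cohorts and endpoint tables
- `twosexlt.lifetable` — the engine; `TwoSexLifeTable` / `LifeTableResults`
- `twosexlt.bootstrap` — vectorised individual-resampling bootstrap
- `twosexlt.groupstats` — assumption-screened ANOVA/Tukey vs KW/Dunn–Holm
- `twosexlt.correlation` — treatment-mean Pearson matrices and heatmaps
- `twosexlt.pipeline`, `twosexlt.cli` — one-command reproducible runs

See `docs/methods.md` for the statistical conventions, generator design
and known limitations.
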