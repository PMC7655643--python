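# Methods

This note documents the models, parameter choices and numerical conventions
behind `liprod`, and what the synthetic tests do and do not demonstrate
about real herd data.

## Data model

The unit of observation is one cow on one of four sampling dates (D1–D4,
spanning autumn of one year to autumn of the next). A record carries farm
identity and management (organic vs. low-input conventional), a canonical
breed code, lactation stage (days in milk), production (milk yield in
L/day; fat+protein solids in kg/day), health (somatic cell count in
10³ cells/ml; count of veterinary or alternative treatments since the
previous date), feeding (concentrate and conserved forage offered, kg/day)
and nine fatty-acid variables (% of total FA, plus the n-6/n-3 ratio). A
record is *complete* — and analyzable — when production, health and the
full FA profile are all present. Season is identified with the four
sampling dates; the study design cannot separate calendar season from
sampling occasion.

Breed codes are parent-sex symmetric: a Jersey sire × Holstein/Friesian
dam and the reverse cross both canonicalize to `HFJE`. Components of
compound labels are ordered by a fixed precedence list (HF, NZF, BF, JE,
SR, SH, AYR, MO, BS, MRI, XX), which reproduces conventional labels like
`HFJE` and `JEAYR` while making the ordering rule total. When parents are
themselves crosses, the label becomes the single strictly-majority breed
plus a trailing `X` (a majority contribution and/or backcross), or `XX`
when no breed dominates — e.g. (JE×SH) × (JE×AYR) → `JEX`. How deeply
bred three-way backcrosses "should" be labelled is not standardized in the
field; the strict-majority rule is this package's choice and is exercised
exhaustively in tests.

Inclusion rule: a breed group enters comparative analysis only if, on at
least one sampling date, it has complete records for ≥ 6 distinct cows on
≥ 3 distinct farms. Cows are counted once per group per date (the rule is
about cows, not samples). The filter is idempotent.

## Scoring

Quintile allocation sorts a variable's records ascending (stable ties by
the (cow_id, date_code) key) and assigns ordinal rank r of n to group
⌊5r/n⌋ + 1, so group sizes never differ by more than one. Desirable
variables score the group number (1–5); undesirable variables score the
reverse (6 − group). Being rank-based, scores are invariant under any
strictly increasing transformation of a variable.

By default quintile groups pool all complete records across dates and
farms (one scheme per variable); a `per_date` scope is available. Pooling
matches the production of a single summary ranking; the within-date
alternative protects against season-driven rank drift. Neither scope is
claimed to be the historically used one — the choice is exposed.

Components: production = yield + solids quintiles (2–10); health =
reversed SCC quintile + a binary untreated indicator (1–6); FA = sum of
four desirable and five reversed undesirable FA quintiles (9–45). The two
composites divide each component by its maximum and weight them
30/50/20 (health emphasis) or 60/30/10 (production emphasis); both have
maximum 1. Scores are computed per record; breed summaries aggregate
records, not per-cow means. Ranking uses the mean composite rounded to
2 decimals, then lower SD, then alphabetical order — documented,
deterministic tie-breaks.

## Synthetic herd generator

The generator is calibrated to the published study population, and its
defaults *are* those study conditions:

* **Roster.** 17 farms (7 organic, 10 low-input) with the printed cow
  counts (40–113; total 1,070), calving patterns and breed lists.
* **Groups.** Cows are allocated to the eight analyzable breed groups
  (AYRX, HF, HFJE, HFSR, JEX, NZFX, SH, SRX) proportionally to the
  published group record counts, restricted per farm to groups whose
  required breeds appear in that farm's list, with largest-remainder
  rounding. Roster tokens without an analysis group (BF, MO, BS, MRI, XX)
  generate no cows by default; they exist for rare-combination injection,
  which appends sub-threshold groups (traits drawn from a donor group) to
  exercise the inclusion filter. A farm whose breed list supports no group
  at all is a configuration error.
* **Trait distributions.** Each (group, trait) pair is parameterized by the
  published mean ± SD. Continuous traits are zero-truncated normals whose
  underlying (μ, σ) are solved numerically so the *truncated* moments equal
  the published values; this matching is feasible whenever SD/mean < ~0.95
  (a left-truncated normal cannot exceed CV = 1), which covers every
  production and FA trait. For the handful of high-CV feeding rows the
  parent normal N(mean, SD) is truncated as-is and the analytically shifted
  moments are exposed via `realized_moments()`; moment-recovery tests check
  against those. SCC is lognormal with σ² = ln(1 + CV²), μ = ln(mean) − σ²/2
  (median exp(μ) ≈ 55 for the most skewed group, close to the published
  medians of 56–89). Treatment counts are negative binomial with
  r = m²/(s² − m), p = m/s², falling back to Poisson when s² ≤ m. The
  n-6/n-3 ratio is always computed from the sampled n-6 and n-3
  percentages, never drawn, so ratio consistency is exact by construction.
* **Hierarchy.** Continuous traits receive an additive farm random
  intercept and a season (date) shift, then are clipped at zero. Default
  SDs are 30% (farm) and 15% (season) of the across-group mean trait SD —
  chosen once as a realistic between-herd spread for grazing systems;
  large enough that PCA clusters records by farm when amplified, small
  enough not to distort the group-level calibration. SCC and treatments
  get no additive shifts (an additive term is the wrong scale for those
  skewed families); their published SDs already reflect between-farm
  spread.
* **Missingness.** Per-date incompleteness probabilities are calibrated so
  the expected complete cohorts match the study's 299/757/772/613 records
  on D1–D4 out of 1,070 cows.
* **Correlations.** Traits are independent by default — the source tables
  publish no covariances — with a Gaussian-copula hook (trait list +
  correlation matrix) for sensitivity analyses.
* **Generation mix.** 20% purebred / 40% F1 / 40% F2+, assigned as cow
  metadata independent of breed label.
* **Determinism.** All randomness flows from one seeded
  `numpy.random.Generator`; identical seeds give byte-identical CSVs.

What the generator does **not** emulate: trait correlations within a cow
(unless a copula is given), lactation curves, calving-date structure,
within-farm diet heterogeneity, genetic/heterosis effects. Consequently a
passing rank-recovery test shows that the published *marginal*
distributions suffice to reproduce ranking endpoints; it does not validate
the index against the joint structure of real milk data, and PCA variance
fractions on default synthetic herds (~11–15% on PC1) are deliberately
lower than the 25–31% seen in correlated field data.

## Ordination

The 13 LI-P variables are standardized per date (mean 0, sample SD 1 with
the n−1 denominator; a constant column is an error naming the column) and
decomposed by eigendecomposition of the correlation matrix. Variance
fraction of component i is λᵢ/Σλ (Σλ equals the variable count to 1e−8).
Loading-vector signs are fixed by making each column's largest-magnitude
entry positive, so results are reproducible across runs and platforms.
Treatments enter as raw counts by default (they are one of the listed LI-P
variables); a flag switches to the binary untreated indicator. Dates with
fewer than 3 complete records are skipped with a logged warning.

## Breed effects

Descriptive summaries report mean ± SD per variable and group, with the
median SCC alongside the mean because a small fraction of very high counts
(mastitic quarters) makes SCC heavily right-skewed. The comparison model is
`trait ~ breed` with crossed random intercepts for farm and season,
estimated by REML (statsmodels `MixedLM` with variance components over a
single trivial group). Optimization tries lbfgs, then bfgs, then powell;
non-convergence after all three raises a diagnostic error, and a singular
variance component is reported as 0 with a warning. The omnibus breed test
is a Wald F (chi-square statistic divided by its degrees of freedom,
referred to an F with residual denominator df); its contract is calibrated
type-I error, verified by a null simulation (~5% rejection at α = 0.05)
rather than allegiance to a named test. With random effects disabled the
fit reduces exactly to OLS and breed estimates equal group means under
balance. No post-hoc pairwise tests are produced: with eight levels and
uneven replication, a family of pairwise comparisons mainly manufactures
false positives; the deliverables are the omnibus test and the descriptive
table. Feeding variables are summarized but never modelled — rations are
set per farm, not per cow, so the independence assumptions fail for them.

## Pipeline and experiments

`run_pipeline` chains generate (or load) → completeness filter → inclusion
→ score → rank → ordinate → breed effects, logs one line per stage, and
writes a manifest (config hash, seed, stage counts, retained groups,
outputs, wall time). Everything except the wall-time field is deterministic
given the seed.

The rank-recovery experiment redraws the eight groups at their published
record counts directly from the trait table (no farm/season effects — the
published mean/SD pairs are marginal over farms), scores each replicate
with pooled quintiles, ranks under both weightings and reports modal and
mean ranks. Two hundred replicates run in seconds; the acceptance script
uses that size. Under identical trait tables for all groups, mean ranks are
uniform — the symmetry null used in testing.

## Numerical conventions and limitations

* CSVs store floats at 6 significant digits; round-trips are exact at that
  precision. Empty cells are missing values, never zeros.
* Quintile allocation requires n ≥ 5 and no missing values (filtering is
  upstream); group sizes differ by ≤ 1 for every n.
* The truncated-normal moment solver caches its solution per distribution
  object; configurations are safe to reuse across replicates.
* Test problem sizes: moment recovery at 2×10⁴ draws per trait (10⁵ for
  the calibration target), rank recovery at 200 replicates, null
  calibration of the mixed model at 120–150 small-cohort refits. These
  sizes keep the full suite under about a minute while leaving binomial/SE
  tolerance bands meaningful.
* Known limitations: no lactation-curve or calving model, no economic
  index, no heterosis computation, no pairwise breed contrasts; PCA figures
  reproduce the plot families structurally, not any particular dataset's
  coordinates.
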