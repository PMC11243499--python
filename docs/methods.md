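# Methods

This note documents the models, conventions and design choices behind
`wbqn`: how questionnaire responses become volumes, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
used throughout.

## Scoring model

Scoring is deterministic arithmetic on a validated participant record.

**Scale mappings.** Each ordinal loss scale is defined by exactly two
published endpoint constants, so the only defensible interpolation is the
two-point line; `map_scale` returns the endpoints verbatim (no floating
drift) and interpolates linearly in between. Questionnaire inputs are
validated to integers within range; the mapping itself is defined on the
continuum, which makes the monotonicity and oracle-equivalence properties
testable on dense grids. The sedentary sweat rate (0.01–0.02 mL/h, i.e. at
most ~0.3 mL over a 16-hour waking day) is physiologically implausible and
is very likely a unit slip in the source instrument; we keep it as published
so that scored outputs are comparable with the instrument's own
calibration, and expose every endpoint in `ScoringConfig` for users who
prefer a corrected rate.

**Intake.** 1 g of food water is counted as 1 mL (water density). Plain
drinking water is kept separate from the nine other beverage categories;
the "liquids except water" total is the exact sum of those categories.
Diary entries referencing a food absent from the composition table reject
the row at validation (no imputation).

**Loss and the lactation term.** The instrument's total loss is
urine + feces + sweat. An opt-in lactation term
(feeds/day × min/feed × milk flow × water fraction of milk) is provided
because for lactating groups the published total losses exceed the sum of
the published component losses by roughly the volume of daily milk
production, suggesting such a term may have been included upstream without
being stated. It stays **off by default** to match the instrument's
explicit definition; the discrepancy is surfaced rather than silently
resolved. Default flow is 6.25 mL milk/min (750 mL/day over 8 × 15 min
feeds), water fraction 0.87.

**Balance and flags.** `balance = intake.total − loss.total` exactly
(property-tested to 1e−9 mL). The binary coding follows the instrument's
convention: 0 marks negative balance, 1 otherwise (zero balance is coded
1). Guideline balance is computed as `intake − recommendation` so that a
positive value is a surplus and the adequacy flag agrees with the sign; the
boundary (intake exactly at the recommendation) counts as adequate.

**Quartiles.** Half-open intervals with boundaries assigned upward:
Q1 < c1 ≤ Q2 < c2 ≤ Q3 < c3 ≤ Q4. Cut-points default to the sample's
25/50/75 quantiles (linear interpolation); fixed cut-points — e.g. the
reference values (−994.47, 33.31, 921.24) mL/day published for this
population — can be set in config.

**Urination frequency.** The questionnaire records frequency (1 … 10+
times/day) while the loss scale has 5 points; no mapping between them is
published. The default lookup {1}→1, {2–3}→2, {4–6}→3, {7–9}→4, {10+}→5 is
an assumption, exposed in config.

## Synthetic cohort generator

The generator emulates the structure of a published cross-sectional cohort
of 529 women: 210 exclusive, 169 mixed, 150 non-breastfeeding (the sizes
consistent with the published total and group percentages; published counts
themselves are internally inconsistent, and the sizes are configurable).

**Calibration.** Only group-level summary statistics (5% trimmed means and
IQRs) are published for this population, so each directly sampled variable
uses a location equal to the published group trimmed mean and a spread
chosen so the simulated IQR approximates the published one. This is
calibration to summaries, not ground truth: passing recovery tests shows
the generator and the scoring/statistics stack are mutually consistent,
not that real cohorts look like this. Published component means do not sum
to published totals (intake or loss), so derived totals in the synthetic
cohort follow from additivity of the calibrated components and differ from
the published totals; in particular the synthetic total loss
(≈ 2600 mL/day) is the sum of the calibrated urine, fecal and sweat
components, and synthetic balances are correspondingly more positive than
the published ones.

**Families.** A deliberate whitelist with closed-form moments: truncated
normal (demographics, food water, activity hours, lactation), lognormal
(beverage volumes, parameterised by arithmetic mean and log-sd), and
categorical (scale points; integer scales use a shifted-binomial pmf whose
expectation hits the calibrated mean exactly — e.g. urine points with mean
1482.5/600 ≈ 2.47). Excretion-point targets are back-solved from the
published mL/day means through the inverse scale mapping.

**What is not emulated.** Real beverage data are zero-inflated (published
IQRs for juice and coffee exceed what any lognormal can produce at the
published mean — IQR/mean > ~0.9 is infeasible); the whitelist
intentionally does not include zero-inflated families, so those spreads
are approximated as closely as lognormal allows. Variables are sampled
independently by default; no published correlation structure exists. An
optional exchangeable Gaussian copula (`liquid_copula_rho`) couples the ten
liquid variables while preserving marginals, for sensitivity analyses.
Seasonality, measurement/recall error and missingness are not modelled.

**Determinism.** Each (group, variable) pair draws from its own PRNG
substream keyed by `(seed, crc32(group), crc32(variable))`, so adding or
re-parameterising one variable never perturbs another, and identical
config + seed yields byte-identical CSV output. Dietary water is sampled
as a per-participant total and then split across six randomly chosen foods
with Dirichlet shares such that grams × water-fraction sums back exactly,
so food-water calibration survives diary decomposition.

**Truth table.** Per-variable means are closed-form (scipy truncated-normal
moments, lognormal mean by construction, categorical dot products).
Population 5% trimmed means, and all summaries of derived quantities
(totals, balance), have no closed form under this generator; they are
computed once from a large fixed-seed reference sample (400,000 per group,
scored by the same vectorised scoring path as real cohorts), giving a
numerical expectation with error well under 2 mL for mL/day variables. The
reference seed is a package constant independent of the cohort seed,
because the truth is a property of the configured distributions, not of a
particular draw.

## Statistics

**Trimmed mean.** floor(0.05·n) observations are removed from each tail
(so nothing is trimmed below n = 20); this matches
`scipy.stats.trim_mean`, which backs the implementation. Other conventions
(rounding, proportional weighting of the boundary observation) exist in
the literature; the floor convention was chosen for its exact,
discrete semantics. The standard error of the trimmed mean uses the
winsorized standard deviation divided by 0.9·√n.

**Kruskal-Wallis** is always tie-corrected (scipy), with the chi-square
reference on k−1 df; the chi-square test of proportions uses no continuity
correction at any table size. A note on small samples: at n = 5 + 5 the
exact permutation null of the KW statistic is discrete, and the chi-square
reference tracks it closely only in the significant tail (deviations of
0.05–0.09 in absolute p are normal mid-range); tests of the p-value
against a permutation null are therefore posed in the tail. Per-variable
p-values are reported raw by default (matching the study design that this
pipeline reproduces); Benjamini–Hochberg adjustment is available as a
config toggle.

**Ordinal regression.** The quartile outcome is modelled with a
proportional-odds cumulative logit,
`P(Y ≤ j | x) = logistic(θⱼ − xᵀβ)`, fitted by maximum likelihood
(statsmodels `OrderedModel`, BFGS with an L-BFGS retry; non-convergence
raises with the optimizer diagnostics). Thresholds are reported on their
natural ordered scale and are strictly increasing by construction. Wald
CIs and p-values are reported; coefficients with |β| > 15 trigger a
separation warning. The default report fits one model per predictor, with
the threshold estimates alongside (matching the customary table layout in
this literature); a joint model is available through the same class.

**Parallel-lines test.** The proportional-odds constraint is tested by a
likelihood ratio against the unconstrained multinomial logit on the same
design, `LR = 2(ℓ_MNL − ℓ_PO)` on (k−2)·p df. The multinomial strictly
nests the cumulative-logit model, so LR ≥ 0 at the optimum; a
cumulative-logit alternative with per-threshold slopes was rejected as the
unconstrained model because it does not guarantee monotone cumulative
probabilities and routinely fails to converge. If the multinomial fit does
not converge the test is reported as indeterminate rather than failing.
Simulation checks use n = 600 per replicate for the type-I-error study
(adequate asymptotics for the LR reference) and n = 2000 for power and
coefficient-recovery studies; recovery uses 500 replicates.

## Known limitations

- Scored outputs inherit every limitation of the instrument itself:
  self-report bias, the coarse ordinal loss scales, and the implausible
  sedentary sweat rate.
- The generator's calibration reproduces group locations, not joint
  distributions; analyses sensitive to tails or dependence (e.g. the
  regression coefficients) should not be interpreted as estimates of the
  real population's values.
- Missing fields reject the affected row at validation (itemised in the
  validation report); there is no imputation.
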