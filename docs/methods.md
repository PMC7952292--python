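# Methods and design notes

This note documents the statistical procedures, the synthetic-population
generator, the numerical conventions, and the design choices that were
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Descriptive comparison of the paired instruments

**Consistency (Janssen scheme).** A (3L, 5L) response pair is consistent
iff it lies in {(1,1), (1,2), (2,2), (2,3), (2,4), (3,4), (3,5)}; the other
8 of the 15 pairs are inconsistent. Per-dimension inconsistency is the
percentage of complete pairs outside the scheme; the headline figure is the
*unweighted* mean over the five dimensions (not pair-weighted), which is
how published per-dimension values aggregate to their printed mean.

**Redistribution percentages** are conditional on *consistent* pairs within
each 3L level, so each 3L level block sums to 100% while inconsistent pairs
are reported separately. Published redistribution tables behave exactly
this way (every level block sums to 100%), which is why this convention was
chosen; the alternative (percentages of all pairs at the 3L level) is not
offered.

**Ceiling effects.** Per-dimension ceilings use all non-missing items of
that dimension; the full-profile ceiling (state 11111) uses complete
profiles. The default significance test is Pearson's χ² without continuity
correction, treating the two instruments' proportions as independent — this
mirrors standard practice in instrument-comparison papers even though the
samples are paired. Because the paired-design objection is real, a McNemar
variant (exact binomial on the discordant cells) is available via
`ceiling(..., method="mcnemar")` and the CLI `--method` flag.

**Denominator policy.** A record with any missing item on an instrument is
excluded from that instrument's *profile-level* analyses; per-dimension
statistics use all non-missing items of that dimension (partially complete
profiles still contribute); pairwise analyses require both members of the
pair. Every report carries its denominators, because denominators are the
recurring ambiguity in this literature.

## Shannon informativity

H′ = −Σ pᵢ log₂ pᵢ with 0·log₂ 0 ≡ 0 by continuity. The variance is the
delta-method (multinomial) expression var H′ = [Σ pᵢ(log₂ pᵢ)² −
(Σ pᵢ log₂ pᵢ)²]/N, and the 95% CI is the symmetric normal approximation
H′ ± 1.96·√var H′ — at general-population sample sizes the intervals are
extremely tight, and no bootstrap is warranted. H′max = log₂ L is carried
at full precision internally (2.3219/1.5850); 2.32/1.58 are display
roundings. The 3L→5L percent change in evenness J′ is computed from
full-precision J′ by default; an "as-printed" mode recomputes it from
3-decimal-rounded J′, since published tables are sometimes rounded before
the division. Neither mode is asserted to be the published arithmetic;
the acceptance worked example uses the rounded-input form, which
reproduces the published self-care value.

## Known-groups, regression and convergent validity

One-way ANOVA per factor (age band, sex, diabetes, SF-1 as a 5-level
factor) and instrument, listwise deletion within the analysis cell.
Directional hypotheses — lower mean index for the oldest vs youngest band,
women vs men, diabetes vs none, worst vs best SF-1 — are evaluated on group
means and reported as pass/fail flags, not as one-sided tests; p-values are
two-sided. Age trends are plain OLS per sex. Convergent validity is
Spearman rank correlation (average ranks for ties), pairwise-complete per
cell; a constant variable in a cell yields an undefined rho reported as
missing with a warning. Signs follow each variable's natural orientation
(dimension levels and SF-1 rise with worse health, EQ VAS and the index
with better health), with an explicit orientation note in the report rather
than any sign flipping.

## Model-based construct validity

The "theoretical model" is a bagged ensemble of regression trees
(scikit-learn `RandomForestRegressor`) predicting the 5L index from five
categorical predictors: age group, sex, education, economic status,
diabetes, level-coded as integers in their canonical category order (the
coding is part of the procedure, since tree splits depend on it).
Defaults: 300 trees, 60/40 seeded uniform train/test split on complete
cases, bootstrap resampling, otherwise scikit-learn regression-forest
defaults (fully grown trees, `min_samples_leaf=1`); the exact
hyperparameters are echoed in the run metadata.

Per-observation errors are *absolute* prediction errors — with a one-sided
95th-percentile criterion, signed errors would make the comparison
meaningless; RMSE keeps its usual squared-error definition. Internal errors
are training-set resubstitution errors (the model's error "on the data from
which it was built"); an out-of-bag mode is provided as a methodologically
stricter alternative. The threshold q95 is the linear-interpolation
empirical 95th percentile of internal errors, and coverage counts held-out
errors **at or below** q95. The non-strict comparison matters only when
errors have atoms: in the noiseless limit all errors are exactly zero, and
a strict inequality would report 0% coverage for a perfect model, which
inverts the statistic's meaning. For continuous outcomes ties have
probability zero and the choice is immaterial.

Behavioural signatures (each verified in the acceptance suite): a
well-specified outcome gives near-overlapping error distributions and
coverage near 95%; destroying all predictor-outcome structure gives
RMSE_int ≈ RMSE_val ≈ sd(outcome) and coverage still near 95% (errors
exchangeable — "no signal" is *not* flagged); a shift confined to held-out
outcomes collapses coverage below 50%. The procedure is descriptive: no
p-value is produced, and it is not a calibrated test.

## Synthetic-population generator

The generator's defaults *are* the emulated study conditions; they are not
tuning knobs. Demographics: age-band weights (19.2, 16.1, 15.4, 17.6,
19.1, 12.6)%, uniform age within band with 70+ capped at 87 (matching the
sample's printed range), 53.2% female, 6.8% diabetes, six education and
seven household-income categories at the published frequencies.

Each respondent carries a latent utility
u = intercept_sex + slope_sex·age + diabetes_effect·[diabetes] + N(0, σ_u),
with the published sex-specific least-squares equations as trend defaults
(male −0.0029·age + 1.0674, female −0.0036·age + 1.0903), σ_u = 0.12, and
diabetes_effect = −0.05 (the published group contrast is smaller for the
5L index, but a clearly resolvable effect is needed for the direction
flags to be a meaningful test at n = 4000; the value is an order-of-
magnitude choice, stated once here). u is clipped to [−1.0, 1.5] — wide
enough never to bind in practice, so the age trend stays linear.

5L items arise from ordered thresholds on a noisy copy of the deficit
1 − u (per-dimension noise sd 0.06). Thresholds were calibrated *once* by
quantile-matching at n = 400 000 under the default demographics against
per-dimension level-proportion targets: level 1 pinned to the published
ceilings (73.7, 90.3, 82.1, 47.2, 57.9)%, levels 2–5 from the published
redistribution column sums renormalised. The single noise scale was chosen
in the same calibration so that the *scored* (toy-value-set) index
preserves the latent male age slope — the threshold staircase attenuates
slopes when the noise is large, and 0.06 makes the attenuation negligible,
which is what lets OLS on generated data recover −0.0029 within its CI.
The frozen constants live in `eq5dval.synthpop.DEFAULT_CUTPOINTS`.

3L items collapse the 5L response: 5L1→3L1, 5L3→3L2, 5L5→3L3
deterministically; 5L2→3L1/3L2 and 5L4→3L2/3L3 with per-dimension split
probabilities computed from the published redistribution counts (e.g.
P(3L1 | consistent 5L2) = 136/440 for mobility). Inconsistent responses
are injected at overall per-dimension rate ε (default 0.044), drawn
uniformly from the 3L levels inconsistent with the respondent's 5L level —
but *only* for respondents above 5L level 1, at the compensated
probability ε·n/n₍5L>1₎, so the marginal inconsistency rate is still
exactly ε. The restriction is deliberate: if flips also hit 5L-best
respondents, a fraction 1−(1−ε)⁵ ≈ 20% of the 5L-11111 group would leave
the 3L ceiling, forcing the full-profile 3L ceiling *below* the 5L one —
the opposite of what paired general-population data show. Substantively,
respondents with no problems on the fine scale essentially never invent
problems on the coarse scale; rating disagreements occur where a rating
judgment exists.

EQ VAS = clip(round(20 + 60·u + N(0, 6)), 0, 100), giving a mean near 75.
SF-1 comes from four thresholds on deficit + N(0, 0.08), calibrated to the
published self-rated-health distribution. Missingness is MCAR at the
instrument level (whole instrument blanked) at rates (0.4, 0.9, 0.1)% —
no mechanism beyond MCAR is emulated because none is published.

**What the generator does not emulate**, hence what passing tests do not
show about real data: the joint dependence among the five dimensions is
induced solely through the shared latent (real data have residual
dimension-specific correlation); inconsistency direction is uniform within
the eligible levels (real inconsistency is patterned); geographic
stratification, survey weights and item-level missingness are absent; and
the 3L per-dimension marginals follow from the collapse model rather than
being calibrated independently, so dimension-level 3L ceilings can sit a
few points above their published counterparts (the published tables are
themselves not perfectly internally consistent between the redistribution
counts and the ceiling percentages for pain/discomfort).

## Problem sizes used in checks

Simulation-based checks run at the emulated study's scale: n = 4000
populations (20 replicates for ceiling ordering, known-groups directions
and the construct-validity battery; 50 for slope recovery), 500 multinomial
draws at N = 4000 for CI coverage, and 300-tree forests throughout. These
sizes give each check a comfortable signal-to-noise margin while the whole
suite runs in well under a minute per battery.

## Known limitations

- The χ² ceiling comparison inherits the independence approximation from
  the practice it mirrors; use the McNemar mode for inference you intend
  to defend.
- The construct-validity statistic has no calibration theory; coverage
  near 95% is a necessary, not sufficient, sign of fit (exchangeable noise
  also produces it).
- Real value sets may include interaction constants beyond the supported
  "any dimension ≥ L" indicators; such sets cannot currently be encoded.
- Reliability and responsiveness are out of scope (they require repeated
  measurements, which the data model does not represent).
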