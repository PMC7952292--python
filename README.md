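# eq5dval

Psychometric validation of the **EQ-5D-5L** questionnaire against its
**EQ-5D-3L** predecessor on paired general-population survey data, as a
tested, reusable Python pipeline.

EQ-5D instruments describe health on five dimensions — mobility, self-care,
usual activities, pain/discomfort, anxiety/depression — at 3 or 5 ordinal
levels, plus a 0–100 visual analogue scale (EQ VAS). A country *value set*
maps each descriptive-system profile to a single utility (index value).
When the same respondents complete both versions, a battery of psychometric
analyses tells you whether the finer-grained 5L version behaves at least as
well as the 3L one. This package implements that battery for analysts of
general-population surveys:

- **Feasibility** — instrument-level missing-data proportions.
- **Redistribution & inconsistency** — how each 3L level maps onto 5L
  levels, with the Janssen consistency scheme
  (3L1→{5L1,5L2}, 3L2→{5L2,5L3,5L4}, 3L3→{5L4,5L5}; 8 of the 15 pairs are
  inconsistent).
- **Ceiling effects** — percent at "no problems" per dimension and at the
  best state 11111, compared between versions (Pearson χ², with a McNemar
  option for the paired design).
- **Informativity** — Shannon index
  H′ = −Σᵢ pᵢ log₂ pᵢ with analytic variance
  var H′ = [Σᵢ pᵢ(log₂ pᵢ)² − (Σᵢ pᵢ log₂ pᵢ)²]/N,
  95% CI H′ ± 1.96·√var H′, and evenness J′ = H′/log₂ L.
- **Known-groups & convergent validity** — one-way ANOVA of index values
  over age group / sex / diabetes / self-rated health (SF-1), per-sex OLS
  age trends, and a Spearman correlation matrix against EQ VAS, the 3L
  dimensions and SF-1.
- **Model-based construct validity** — a "theoretical model" of the 5L
  index (random forest, 300 trees, on age group, sex, education, economic
  status, diabetes) fitted on a 60% split; construct validity is judged by
  comparing internal (training) and held-out absolute-error distributions:
  RMSE_int vs RMSE_val, and the share of held-out errors at or below the
  95th percentile of internal errors.

Because general-population microdata are rarely shareable, the package
bundles a calibrated **synthetic-population generator**
(`eq5dval.synthpop`) that reproduces the structure of a 2014 Polish adult
survey (N = 3978, ages 18–87, 53.2% female, 6.8% diabetes, published
per-dimension ceilings, age-utility trends, 4.4% 3L/5L inconsistency,
realistic missingness), so every stage of the pipeline is exercised and
tested end to end without external data.

## Data formats

Surveys are delimited text (comma default, tab accepted), UTF-8, header
row, missing values as empty fields, with columns

```
id, age, sex, education, economic_status, diabetes,
mo5, sc5, ua5, pd5, ad5,   # EQ-5D-5L items, levels 1-5
mo3, sc3, ua3, pd3, ad3,   # EQ-5D-3L items, levels 1-3
eq_vas, sf1
```

Extra columns pass through untouched. Value sets are delimited text with a
`# key=value` header block (version, label, full_health_value, optional
threshold-indicator extra terms) and `dimension,level,decrement` rows; real
country coefficients are supplied by the user as files (a synthetic "toy"
set with equal 0.05 level steps is bundled for testing —
`eq5dval.toy_value_set()`).

## Worked example

```sh
python analysis/01_simulate_population.py
python analysis/02_descriptive_comparison.py
python analysis/05_construct_validity_rf.py
```

prints (seed 42, N = 3978):

```
female: 52.5%  diabetes: 6.8%
missing: 5L 0.4%  3L 1.4%  VAS 0.1%
  mean inconsistency 4.5%
  profile ceiling: 3L 48.5% vs 5L 42.8% (p = 3.3e-07) — the coarser
  instrument shows the higher ceiling, as hypothesised
  male: index = -0.0029*age + 1.0347 (n=1883)
RMSE_int 0.138, RMSE_val 0.162: held-out error close to the model's own error
92.6% of held-out errors fall at or below the 95th percentile of internal
errors (0.307 utility units)
```

Reading this: about 4.5% of paired responses violate the Janssen scheme
(the generator's target rate is 4.4%); the 3L best state is reported 5.7
points more often than the 5L one, the classic ceiling advantage of the
finer scale; the male index loses ~0.003 utility per year of age; and the
held-out error distribution of the random-forest model nearly matches its
internal one (92.6% below the internal 95th percentile), the signature of
an instrument consistent with the socio-demographic "theory" encoded by
the model. The remaining drivers (`03`, `04`) write the informativity and
known-groups/convergent tables under `results/`.

The same operations are scriptable via the CLI, e.g.

```sh
eq5d-validate simulate --n 3978 --seed 42 --out survey.csv
eq5d-validate feasibility survey.csv
eq5d-validate all survey.csv --vs3 vs3.csv --vs5 vs5.csv --out report/
```

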