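"""Synthetic general-population survey generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without external microdata:

* demographics drawn from the study sample's published composition
  (age-band weights, 53.2% female, 6.8% diabetes, education and income
  bands);
* a latent utility ``u = intercept_sex + slope_sex*age +
  diabetes_effect*[diabetes] + N(0, latent_sd)`` whose sex-specific age
  trends default to the published least-squares equations;
* 5L items from ordered thresholds ("cutpoints") on a per-dimension noisy
  copy of the deficit 1-u, with default cutpoints calibrated so the
  per-dimension "no problems" proportions match the published ceilings and
  the toy-value-set index preserves the latent age slope;
* 3L items by collapsing the 5L response (5L1->3L1; 5L2->3L1/3L2,
  5L3->3L2, 5L4->3L2/3L3, 5L5->3L3, with per-dimension split probabilities
  taken from the published redistribution table), plus controlled
  inconsistent responses at overall per-dimension rate ``inconsistency_rate``.
  Inconsistent flips are restricted to responses above 5L level 1 at a
  compensated probability, so respondents at the 5L best state always
  collapse to the 3L best state — which is what keeps the full-profile 3L
  ceiling above the 5L one, as observed in real paired data;
* EQ VAS as a linear-plus-noise readout of u, clipped to 0..100; SF-1 from
  thresholds on a noisy deficit; instrument-level MCAR missingness.

Everything is reproducible from (config, seed): identical configs give
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .datamodel import (
    AGE_GROUP_LABELS,
    COLS_3L,
    COLS_5L,
    DIMENSIONS,
    ECONOMIC_LEVELS,
    EDUCATION_LEVELS,
    SurveyDataset,
)

_AGE_BOUNDS = ((18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 87))

# Cutpoints on the noisy deficit 1-u mapping latent health to 5L levels.
# Calibrated once (quantile matching at n=400k under the default
# demographics) so the marginal level distribution of each dimension matches
# its published target; see docs/methods.md.
DEFAULT_CUTPOINTS: dict[str, tuple[float, float, float, float]] = {
    "mobility": (0.177469, 0.240839, 0.301209, 0.473722),
    "self_care": (0.275550, 0.328782, 0.398530, 0.499035),
    "usual_activities": (0.219465, 0.292936, 0.362492, 0.474832),
    "pain_discomfort": (0.072800, 0.187862, 0.296262, 0.493964),
    "anxiety_depression": (0.113117, 0.250390, 0.350752, 0.489571),
}
# Noise scale on the per-dimension deficit copy; a single calibrated value.
DEFAULT_DIMENSION_NOISE_SD = 0.06

# SF-1 thresholds on deficit + N(0, sf1 noise): calibrated to the published
# self-rated-health distribution (6.2/25.3/44.2/20.4/3.9%).
DEFAULT_SF1_CUTPOINTS: tuple[float, float, float, float] = (
    -0.157256, 0.007389, 0.192728, 0.360085,
)
DEFAULT_SF1_NOISE_SD = 0.08

_DEFAULT_COLLAPSE_2_TO_1 = {
    "mobility": 136 / 440,
    "self_care": 37 / 164,
    "usual_activities": 99 / 361,
    "pain_discomfort": 300 / 1081,
    "anxiety_depression": 391 / 1076,
}
_DEFAULT_COLLAPSE_4_TO_2 = {
    "mobility": 233 / 242,
    "self_care": 36 / 48,
    "usual_activities": 63 / 92,
    "pain_discomfort": 204 / 274,
    "anxiety_depression": 93 / 119,
}

# 3L levels that are inconsistent with each 5L level under the Janssen scheme.
_INCONSISTENT_3L = {1: (2, 3), 2: (3,), 3: (1, 3), 4: (1,), 5: (1, 2)}


class ConfigError(ValueError):
    """Generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic survey.

    Defaults reproduce the emulated study sample; see module docstring.
    """

    n: int = reference.N_SAMPLE
    seed: int = 0
    age_group_weights: tuple = reference.AGE_GROUP_WEIGHTS
    female_prop: float = reference.FEMALE_PROP
    diabetes_prop: float = reference.DIABETES_PROP
    education_weights: tuple = reference.EDUCATION_WEIGHTS
    economic_weights: tuple = reference.ECONOMIC_WEIGHTS
    # per-sex (slope per year of age, intercept) of the latent utility
    latent_trend: dict = field(
        default_factory=lambda: dict(reference.LATENT_TRENDS)
    )
    latent_sd: float = 0.12
    diabetes_effect: float = -0.05
    dimension_cutpoints: dict = field(
        default_factory=lambda: dict(DEFAULT_CUTPOINTS)
    )
    dimension_noise_sd: float = DEFAULT_DIMENSION_NOISE_SD
    inconsistency_rate: float = 0.044
    collapse_prob_2_to_1: dict = field(
        default_factory=lambda: dict(_DEFAULT_COLLAPSE_2_TO_1)
    )
    collapse_prob_4_to_2: dict = field(
        default_factory=lambda: dict(_DEFAULT_COLLAPSE_4_TO_2)
    )
    vas_link: tuple = (60.0, 20.0, 6.0)  # (scale, offset, noise sd)
    sf1_cutpoints: tuple = DEFAULT_SF1_CUTPOINTS
    sf1_noise_sd: float = DEFAULT_SF1_NOISE_SD
    missing_rates: tuple = reference.MISSING_RATES  # (5L, 3L, VAS)
    latent_bounds: tuple = (-1.0, 1.5)

    def validate(self) -> None:
        for name, weights, k in (
            ("age_group_weights", self.age_group_weights, 6),
            ("education_weights", self.education_weights, len(EDUCATION_LEVELS)),
            ("economic_weights", self.economic_weights, len(ECONOMIC_LEVELS)),
        ):
            if len(weights) != k:
                raise ConfigError(f"{name} must have {k} entries")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(weights)})")
            if any(w < 0 for w in weights):
                raise ConfigError(f"{name} must be nonnegative")
        for name, p in (("female_prop", self.female_prop),
                        ("diabetes_prop", self.diabetes_prop),
                        ("inconsistency_rate", self.inconsistency_rate)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n < 0:
            raise ConfigError("n must be nonnegative")
        if self.latent_sd < 0 or self.dimension_noise_sd < 0 or self.sf1_noise_sd < 0:
            raise ConfigError("noise scales must be nonnegative")
        for dim in DIMENSIONS:
            cuts = self.dimension_cutpoints.get(dim)
            if cuts is None or len(cuts) != 4:
                raise ConfigError(f"dimension_cutpoints[{dim!r}] must have 4 entries")
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ConfigError(f"cutpoints for {dim!r} must be strictly increasing")
            for probs in (self.collapse_prob_2_to_1, self.collapse_prob_4_to_2):
                if not 0.0 <= probs[dim] <= 1.0:
                    raise ConfigError(f"collapse probability for {dim!r} outside [0, 1]")
        if any(b <= a for a, b in zip(self.sf1_cutpoints, self.sf1_cutpoints[1:])):
            raise ConfigError("sf1_cutpoints must be strictly increasing")
        if len(self.missing_rates) != 3 or any(
            not 0.0 <= r <= 1.0 for r in self.missing_rates
        ):
            raise ConfigError("missing_rates must be three proportions")
        for sex in ("male", "female"):
            if sex not in self.latent_trend or len(self.latent_trend[sex]) != 2:
                raise ConfigError(f"latent_trend must map {sex!r} to (slope, intercept)")


def truth_record(config: GeneratorConfig) -> dict:
    """Machine-readable echo of every generating parameter."""
    rec = dataclasses.asdict(config)
    rec["latent_trend"] = {s: tuple(v) for s, v in rec["latent_trend"].items()}
    return rec


def generate_population(config: GeneratorConfig) -> SurveyDataset:
    """Draw a survey dataset under ``config``; see the module docstring for
    the per-record procedure.  Fully reproducible given the config seed."""
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)

    # (1) demographics
    group = rng.choice(6, size=n, p=np.asarray(config.age_group_weights, dtype=float))
    lo = np.array([b[0] for b in _AGE_BOUNDS])
    hi = np.array([b[1] for b in _AGE_BOUNDS])
    age = rng.integers(lo[group], hi[group] + 1) if n else np.zeros(0, dtype=int)
    female = rng.random(n) < config.female_prop
    education = rng.choice(
        len(EDUCATION_LEVELS), size=n, p=np.asarray(config.education_weights, float)
    )
    economic = rng.choice(
        len(ECONOMIC_LEVELS), size=n, p=np.asarray(config.economic_weights, float)
    )
    diabetes = rng.random(n) < config.diabetes_prop

    # (2) latent utility
    slope_m, int_m = config.latent_trend["male"]
    slope_f, int_f = config.latent_trend["female"]
    slope = np.where(female, slope_f, slope_m)
    intercept = np.where(female, int_f, int_m)
    u = intercept + slope * age + config.diabetes_effect * diabetes
    u = u + rng.normal(0.0, config.latent_sd, size=n)
    u = np.clip(u, config.latent_bounds[0], config.latent_bounds[1])
    deficit = 1.0 - u

    # (3) 5L items from dimension cutpoints on a noisy deficit copy
    levels5 = {}
    for dim in DIMENSIONS:
        x = deficit + rng.normal(0.0, config.dimension_noise_sd, size=n)
        cuts = np.asarray(config.dimension_cutpoints[dim], dtype=float)
        levels5[dim] = 1 + np.searchsorted(cuts, x, side="left")

    # (4) 3L items: consistent collapse, plus inconsistent flips restricted
    # to 5L levels > 1 at a compensated probability so the marginal
    # inconsistency rate per dimension is inconsistency_rate.
    eps = config.inconsistency_rate
    levels3 = {}
    for dim in DIMENSIONS:
        l5 = levels5[dim]
        split2 = rng.random(n) < config.collapse_prob_2_to_1[dim]
        split4 = rng.random(n) < config.collapse_prob_4_to_2[dim]
        l3 = np.select(
            [l5 == 1, l5 == 2, l5 == 3, l5 == 4, l5 == 5],
            [1, np.where(split2, 1, 2), 2, np.where(split4, 2, 3), 3],
        )
        flip_u = rng.random(n)
        pick = rng.integers(0, 2, size=n)  # chooses within 2-element sets
        if eps > 0 and n > 0:
            eligible = l5 > 1
            n_eligible = int(eligible.sum())
            if n_eligible > 0:
                eps_eff = min(1.0, eps * n / n_eligible)
                flip = eligible & (flip_u < eps_eff)
                for lev in (2, 3, 4, 5):
                    idx = flip & (l5 == lev)
                    options = _INCONSISTENT_3L[lev]
                    if len(options) == 1:
                        l3[idx] = options[0]
                    else:
                        l3[idx] = np.where(
                            pick[idx] == 0, options[0], options[1]
                        )
        levels3[dim] = l3

    # (5) EQ VAS
    scale, offset, vas_sd = config.vas_link
    vas = np.clip(
        np.round(offset + scale * u + rng.normal(0.0, vas_sd, size=n)), 0, 100
    ).astype(int) if n else np.zeros(0, dtype=int)

    # (6) SF-1
    x_sf = deficit + rng.normal(0.0, config.sf1_noise_sd, size=n)
    sf1 = 1 + np.searchsorted(np.asarray(config.sf1_cutpoints, float), x_sf,
                              side="left")

    # (7) instrument-level MCAR missingness
    miss5 = rng.random(n) < config.missing_rates[0]
    miss3 = rng.random(n) < config.missing_rates[1]
    missv = rng.random(n) < config.missing_rates[2]

    df = pd.DataFrame(
        {
            "id": [f"s{i:06d}" for i in range(n)],
            "age": pd.array(age, dtype="Int64"),
            "sex": np.where(female, "female", "male"),
            "education": np.asarray(EDUCATION_LEVELS, dtype=object)[education],
            "economic_status": np.asarray(ECONOMIC_LEVELS, dtype=object)[economic],
            "diabetes": pd.array(diabetes, dtype="boolean"),
        }
    )
    for dim, c5 in zip(DIMENSIONS, COLS_5L):
        df[c5] = pd.array(np.where(miss5, pd.NA, levels5[dim]), dtype="Int64")
    for dim, c3 in zip(DIMENSIONS, COLS_3L):
        df[c3] = pd.array(np.where(miss3, pd.NA, levels3[dim]), dtype="Int64")
    df["eq_vas"] = pd.array(np.where(missv, pd.NA, vas), dtype="Int64")
    df["sf1"] = pd.array(sf1, dtype="Int64")

    meta = {"source": "eq5dval.synthpop", "seed": config.seed,
            "generator": truth_record(config)}
    return SurveyDataset(df, meta)
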