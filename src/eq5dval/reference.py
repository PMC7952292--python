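"""Published summary statistics from a 2014 Polish adult general-population
EQ-5D survey (N = 3978, ages 18-87).

These numbers play two roles in the package:

* calibration targets and defaults for the synthetic-population generator
  (:mod:`eq5dval.synthpop`) — sample composition, per-dimension ceilings,
  age-utility trends, inconsistency and missing-data rates;
* worked-example inputs: the published redistribution table can be expanded
  back into respondent-level 3L/5L response pairs
  (:func:`reconstruct_pair_dataset`), on which the package's own
  redistribution analysis reproduces the published percentages.

Only summary tables are stored here; no respondent-level data from the
original survey exists in this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    COLS_3L,
    COLS_5L,
    DIMENSIONS,
    SurveyDataset,
)

# --- Sample composition -----------------------------------------------------

N_SAMPLE = 3978

AGE_GROUP_WEIGHTS = (0.192, 0.161, 0.154, 0.176, 0.191, 0.126)
FEMALE_PROP = 0.532
DIABETES_PROP = 0.068

EDUCATION_WEIGHTS = (0.171, 0.249, 0.329, 0.030, 0.213, 0.008)
ECONOMIC_WEIGHTS = (0.100, 0.096, 0.138, 0.178, 0.216, 0.087, 0.185)

# Self-rated general health (SF-1): excellent .. poor.
SF1_PROPS = (0.062, 0.253, 0.442, 0.204, 0.039)

# Instrument-level missing-data proportions: EQ-5D-5L, EQ-5D-3L, EQ VAS.
MISSING_RATES = (0.004, 0.009, 0.001)

# Least-squares age trends of the 5L index value, by sex: (slope/year, intercept).
LATENT_TRENDS = {"male": (-0.0029, 1.0674), "female": (-0.0036, 1.0903)}

# --- Ceiling effects (percent at "no problems" / state 11111) ---------------

CEILING_3L = {
    "mobility": 74.3,
    "self_care": 90.9,
    "usual_activities": 82.6,
    "pain_discomfort": 47.8,
    "anxiety_depression": 58.5,
    "health_state_11111": 46.6,
}
CEILING_5L = {
    "mobility": 73.7,
    "self_care": 90.3,
    "usual_activities": 82.1,
    "pain_discomfort": 47.2,
    "anxiety_depression": 57.9,
    "health_state_11111": 38.0,
}

# --- Redistribution table ----------------------------------------------------
# Consistent 3L->5L cell counts per dimension, plus the published per-dimension
# inconsistency percentage.  Cell keys are (3L level, 5L level).

REDISTRIBUTION_COUNTS: dict[str, dict[tuple[int, int], int]] = {
    "mobility": {(1, 1): 2857, (1, 2): 136,
                 (2, 2): 304, (2, 3): 270, (2, 4): 233,
                 (3, 4): 9, (3, 5): 15},
    "self_care": {(1, 1): 3521, (1, 2): 37,
                  (2, 2): 127, (2, 3): 109, (2, 4): 36,
                  (3, 4): 12, (3, 5): 8},
    "usual_activities": {(1, 1): 3066, (1, 2): 99,
                         (2, 2): 262, (2, 3): 178, (2, 4): 63,
                         (3, 4): 29, (3, 5): 14},
    "pain_discomfort": {(1, 1): 1780, (1, 2): 300,
                        (2, 2): 781, (2, 3): 617, (2, 4): 204,
                        (3, 4): 70, (3, 5): 10},
    "anxiety_depression": {(1, 1): 2172, (1, 2): 391,
                           (2, 2): 685, (2, 3): 349, (2, 4): 93,
                           (3, 4): 26, (3, 5): 11},
}

INCONSISTENCY_PCT = {
    "mobility": 3.3,
    "self_care": 2.5,
    "usual_activities": 5.8,
    "pain_discomfort": 4.8,
    "anxiety_depression": 5.7,
}
MEAN_INCONSISTENCY_PCT = 4.4

# --- Shannon informativity (published per-dimension values) ------------------

SHANNON_H = {
    "mobility": {"3L": 0.825, "5L": 1.253},
    "self_care": {"3L": 0.487, "5L": 0.587},
    "usual_activities": {"3L": 0.787, "5L": 0.932},
    "pain_discomfort": {"3L": 1.139, "5L": 1.765},
    "anxiety_depression": {"3L": 1.004, "5L": 1.495},
}
SHANNON_J = {
    "mobility": {"3L": 0.522, "5L": 0.540},
    "self_care": {"3L": 0.308, "5L": 0.253},
    "usual_activities": {"3L": 0.498, "5L": 0.402},
    "pain_discomfort": {"3L": 0.721, "5L": 0.761},
    "anxiety_depression": {"3L": 0.635, "5L": 0.645},
}

# --- Random-forest construct-validity reference values ------------------------

RF_REFERENCE = {"rmse_int": 0.095, "rmse_val": 0.121,
                "q95_int": 0.125, "coverage_pct": 85.6}

EQ_VAS_MEAN = 74.9


# --- Derived helpers ----------------------------------------------------------


def inconsistent_pair_counts() -> dict[str, int]:
    """Number of inconsistent pairs per dimension implied by the published
    consistent-cell counts and inconsistency percentages."""
    out = {}
    for dim in DIMENSIONS:
        consistent = sum(REDISTRIBUTION_COUNTS[dim].values())
        pct = INCONSISTENCY_PCT[dim]
        out[dim] = int(round(consistent * pct / (100.0 - pct)))
    return out


def five_level_marginals() -> dict[str, np.ndarray]:
    """Per-dimension 5L level proportions used as generator calibration
    targets: level 1 pinned to the published ceiling, levels 2-5 from the
    redistribution column sums, renormalised."""
    out = {}
    for dim in DIMENSIONS:
        cells = REDISTRIBUTION_COUNTS[dim]
        col = np.zeros(5)
        for (_, l5), n in cells.items():
            col[l5 - 1] += n
        p1 = CEILING_5L[dim] / 100.0
        rest = col[1:] / col.sum()
        rest = rest * (1.0 - p1) / rest.sum()
        out[dim] = np.concatenate([[p1], rest])
    return out


def collapse_probabilities() -> tuple[dict[str, float], dict[str, float]]:
    """Per-dimension conditional collapse probabilities implied by the
    published redistribution counts: P(3L1 | consistent 5L2) and
    P(3L2 | consistent 5L4)."""
    p2_to_1, p4_to_2 = {}, {}
    for dim in DIMENSIONS:
        c = REDISTRIBUTION_COUNTS[dim]
        p2_to_1[dim] = c[(1, 2)] / (c[(1, 2)] + c[(2, 2)])
        p4_to_2[dim] = c[(2, 4)] / (c[(2, 4)] + c[(3, 4)])
    return p2_to_1, p4_to_2


_INCONSISTENT_CELLS = {
    dim: sorted(
        (l3, l5)
        for l3 in (1, 2, 3)
        for l5 in (1, 2, 3, 4, 5)
        if (l3, l5) not in {(1, 1), (1, 2), (2, 2), (2, 3), (2, 4), (3, 4), (3, 5)}
    )
    for dim in DIMENSIONS
}


def reconstruct_pair_dataset() -> SurveyDataset:
    """Expand the published redistribution table into respondent-level
    3L/5L pairs.

    Consistent cells get exactly their published counts.  Inconsistent pairs
    (whose cell-level breakdown was not published) are spread round-robin
    over the eight inconsistent cells so that each dimension's total matches
    the published inconsistency percentage.  Dimensions have different pair
    counts; shorter dimensions are padded with missing items.  The joint
    distribution across dimensions is arbitrary — only per-dimension pair
    tables are meaningful in the result.
    """
    n_inc = inconsistent_pair_counts()
    per_dim_pairs: dict[str, list[tuple[int, int]]] = {}
    for dim in DIMENSIONS:
        pairs: list[tuple[int, int]] = []
        for (l3, l5), n in sorted(REDISTRIBUTION_COUNTS[dim].items()):
            pairs.extend([(l3, l5)] * n)
        cells = _INCONSISTENT_CELLS[dim]
        for i in range(n_inc[dim]):
            pairs.append(cells[i % len(cells)])
        per_dim_pairs[dim] = pairs

    n_max = max(len(p) for p in per_dim_pairs.values())
    data: dict[str, list] = {c3: [] for c3 in COLS_3L}
    data.update({c5: [] for c5 in COLS_5L})
    for dim, c3, c5 in zip(DIMENSIONS, COLS_3L, COLS_5L):
        pairs = per_dim_pairs[dim]
        l3s = [p[0] for p in pairs] + [pd.NA] * (n_max - len(pairs))
        l5s = [p[1] for p in pairs] + [pd.NA] * (n_max - len(pairs))
        data[c3] = l3s
        data[c5] = l5s

    df = pd.DataFrame(data)
    for col in list(COLS_3L) + list(COLS_5L):
        df[col] = df[col].astype("Int64")
    df.insert(0, "id", [f"r{i:05d}" for i in range(n_max)])
    df.insert(1, "age", 50)
    df.insert(2, "sex", "female")
    df.insert(3, "education", "secondary")
    df.insert(4, "economic_status", "181-240")
    df.insert(5, "diabetes", pd.Series([False] * n_max, dtype="boolean"))
    df["eq_vas"] = pd.Series([pd.NA] * n_max, dtype="Int64")
    df["sf1"] = pd.Series([pd.NA] * n_max, dtype="Int64")
    return SurveyDataset(df, {"source": "published redistribution table"})
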