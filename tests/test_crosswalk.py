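"""Janssen consistency classification, redistribution, and ceiling effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eq5dval import (
    GeneratorConfig,
    ceiling,
    classify_pair,
    generate_population,
    redistribution,
)
from eq5dval.datamodel import COLS_3L, COLS_5L, DIMENSIONS, SurveyDataset


def _pairs_dataset(pairs_by_dim):
    """Build a survey whose (3L, 5L) pairs per dimension are as given."""
    n = max((len(p) for p in pairs_by_dim.values()), default=5)
    data = {}
    for dim, c3, c5 in zip(DIMENSIONS, COLS_3L, COLS_5L):
        pairs = pairs_by_dim.get(dim, [(1, 1)] * n)
        pairs = list(pairs) + [(1, 1)] * (n - len(pairs))
        data[c3] = pd.array([p[0] for p in pairs], dtype="Int64")
        data[c5] = pd.array([p[1] for p in pairs], dtype="Int64")
    df = pd.DataFrame(data)
    df.insert(0, "id", [str(i) for i in range(n)])
    df.insert(1, "age", 40)
    df.insert(2, "sex", "male")
    df.insert(3, "education", "higher")
    df.insert(4, "economic_status", ">360")
    df.insert(5, "diabetes", pd.array([False] * n, dtype="boolean"))
    df["eq_vas"] = pd.array([80] * n, dtype="Int64")
    df["sf1"] = pd.array([2] * n, dtype="Int64")
    return SurveyDataset(df, {})


# ---------------------------------------------------------------------------
# classify_pair
# ---------------------------------------------------------------------------

# Independently coded lookup of the Janssen scheme: 3L1 -> 5L{1,2},
# 3L2 -> 5L{2,3,4}, 3L3 -> 5L{4,5}.
_LOOKUP = {1: {1, 2}, 2: {2, 3, 4}, 3: {4, 5}}


def test_classifier_agrees_with_independent_lookup_on_all_15_pairs():
    n_consistent = 0
    for l3 in (1, 2, 3):
        for l5 in (1, 2, 3, 4, 5):
            expected = "consistent" if l5 in _LOOKUP[l3] else "inconsistent"
            assert classify_pair(l3, l5) == expected
            n_consistent += expected == "consistent"
    assert n_consistent == 7


@pytest.mark.parametrize("l3,l5", [(0, 1), (4, 1), (1, 0), (1, 6)])
def test_classifier_rejects_out_of_range(l3, l5):
    with pytest.raises(ValueError):
        classify_pair(l3, l5)


# ---------------------------------------------------------------------------
# redistribution
# ---------------------------------------------------------------------------


def test_consistent_pct_conditional_on_3l_level():
    ds = _pairs_dataset({"pain_discomfort": [(3, 4)] * 70 + [(3, 5)] * 10})
    rep = redistribution(ds)
    pd_ = rep.dimensions["pain_discomfort"]
    assert pd_.consistent_pct[(3, 4)] == pytest.approx(87.5)
    assert pd_.consistent_pct[(3, 5)] == pytest.approx(12.5)


def test_cell_counts_sum_to_n_pairs(medium_survey):
    rep = redistribution(medium_survey)
    for dim in DIMENSIONS:
        d = rep.dimensions[dim]
        assert int(d.counts.to_numpy().sum()) == d.n_pairs


def test_consistent_pct_blocks_sum_to_100(medium_survey):
    rep = redistribution(medium_survey)
    for dim in DIMENSIONS:
        d = rep.dimensions[dim]
        for l3 in (1, 2, 3):
            total = sum(
                pct for (a, _), pct in d.consistent_pct.items()
                if a == l3 and not np.isnan(pct)
            )
            assert total == pytest.approx(100.0, abs=0.1)


def test_mean_is_unweighted_dimension_mean():
    pairs = {
        "mobility": [(1, 1)] * 9 + [(1, 5)],          # 10% inconsistent
        "self_care": [(1, 1)] * 4 + [(1, 5)],         # 20% inconsistent
    }
    rep = redistribution(_pairs_dataset(pairs))
    by_dim = rep.inconsistency_by_dimension()
    assert rep.mean_inconsistency_pct == pytest.approx(
        np.mean(list(by_dim.values()))
    )


def test_statistics_invariant_under_record_shuffling(medium_survey):
    rep1 = redistribution(medium_survey)
    shuffled = SurveyDataset(
        medium_survey.frame.sample(frac=1.0, random_state=3).reset_index(drop=True),
        {},
    )
    rep2 = redistribution(shuffled)
    for dim in DIMENSIONS:
        assert rep1.dimensions[dim].counts.equals(rep2.dimensions[dim].counts)
    assert rep1.mean_inconsistency_pct == rep2.mean_inconsistency_pct


def test_dimension_with_no_pairs_errors():
    ds = _pairs_dataset({})
    df = ds.frame.copy()
    df["mo3"] = pd.array([pd.NA] * len(df), dtype="Int64")
    with pytest.raises(ValueError, match="mobility"):
        redistribution(SurveyDataset(df, {}))


# ---------------------------------------------------------------------------
# ceiling
# ---------------------------------------------------------------------------


def test_all_best_states_give_full_ceilings():
    ds = _pairs_dataset({dim: [(1, 1)] * 5 for dim in DIMENSIONS})
    rep = ceiling(ds)
    assert (rep.table["ceiling_3l"] == 100.0).all()
    assert (rep.table["ceiling_5l"] == 100.0).all()
    assert (rep.table["change"] == 0.0).all()


def test_profile_ceiling_contrast_with_chi_square_oracle():
    # 466/1000 at the 3L best state vs 380/1000 at the 5L best state
    pairs = {dim: [] for dim in DIMENSIONS}
    for i in range(1000):
        l5 = 1 if i < 380 else 2
        l3 = 1 if i < 466 else 2
        for dim in DIMENSIONS:
            pairs[dim].append((l3, l5))
    rep = ceiling(_pairs_dataset(pairs))
    row = rep.table.loc["health_state_11111"]
    assert row["change"] == pytest.approx(8.6)
    # independent oracle: textbook Pearson chi-square on the 2x2 table
    obs = np.array([[466, 534], [380, 620]])
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    chi2 = ((obs - expected) ** 2 / expected).sum()
    p_oracle = stats.chi2.sf(chi2, df=1)
    assert row["chi2_p"] == pytest.approx(p_oracle, rel=1e-10)
    assert row["chi2_p"] < 0.01


def test_single_record_degenerate_denominators():
    ds = _pairs_dataset({dim: [(1, 2)] for dim in DIMENSIONS})
    rep = ceiling(ds)
    row = rep.table.loc["health_state_11111"]
    assert row["ceiling_3l"] == 100.0
    assert row["ceiling_5l"] == 0.0
    assert row["change"] == 100.0


def test_mcnemar_method_runs_on_paired_data(medium_survey):
    rep = ceiling(medium_survey, method="mcnemar")
    p = rep.table.loc["health_state_11111", "chi2_p"]
    assert 0.0 <= p <= 1.0
    assert rep.method == "mcnemar"


def test_ceiling_hypothesis_on_generated_defaults():
    # full-profile ceiling of the coarse instrument is never below the
    # fine-grained one on default synthetic data
    for seed in range(20):
        ds = generate_population(GeneratorConfig(n=4000, seed=300 + seed))
        row = ceiling(ds).table.loc["health_state_11111"]
        assert row["ceiling_3l"] >= row["ceiling_5l"]
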