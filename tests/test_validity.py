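"""Known-groups ANOVA, age regression, and Spearman convergent validity."""

import numpy as np
import pandas as pd
import pytest

from eq5dval import (
    GeneratorConfig,
    age_regression,
    convergent_matrix,
    generate_population,
    index_column,
    known_groups,
    toy_value_set,
)
from eq5dval.datamodel import DIMENSIONS, SurveyDataset
from eq5dval.validity import KNOWN_GROUP_FACTORS


def _index_like(dataset, values):
    return pd.Series(np.asarray(values, dtype=float), index=dataset.frame.index)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def anova_oracle(samples):
    """Textbook one-way ANOVA: F = MS_between / MS_within."""
    k = len(samples)
    n = sum(len(s) for s in samples)
    grand = np.mean(np.concatenate(samples))
    ss_between = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ss_within = sum(((s - np.mean(s)) ** 2).sum() for s in samples)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def test_identical_groups_give_zero_F(small_survey):
    idx = _index_like(small_survey, [0.9] * small_survey.n)
    rep = known_groups(small_survey, idx, idx)
    for factor in rep.results.values():
        for fa in factor.values():
            assert fa.F == 0.0


def test_anova_matches_textbook_oracle():
    rng = np.random.default_rng(0)
    samples = [
        1.0 + rng.normal(0, 1e-3, 3),
        0.9 + rng.normal(0, 1e-3, 3),
        0.8 + rng.normal(0, 1e-3, 3),
    ]
    ds = generate_population(GeneratorConfig(n=9, seed=0))
    df = ds.frame.copy()
    df["sf1"] = pd.array([1, 1, 1, 2, 2, 2, 3, 3, 3], dtype="Int64")
    ds = SurveyDataset(df, {})
    idx = _index_like(ds, np.concatenate(samples))
    rep = known_groups(ds, idx, idx)
    fa = rep.results["sf1"]["5L"]
    assert fa.F == pytest.approx(anova_oracle(samples), rel=1e-9)


def test_single_group_factor_skipped_with_warning(small_survey):
    df = small_survey.frame.copy()
    df["sex"] = "female"
    ds = SurveyDataset(df, {})
    idx = _index_like(ds, np.linspace(0, 1, ds.n))
    with pytest.warns(UserWarning, match="sex"):
        rep = known_groups(ds, idx, idx)
    assert "sex" not in rep.results
    assert "sex/5L" in rep.skipped


def test_known_groups_directions_on_synthetic_defaults():
    ds = generate_population(GeneratorConfig(n=4000, seed=77))
    i5 = index_column(ds, toy_value_set("5L"))
    i3 = index_column(ds, toy_value_set("3L"))
    rep = known_groups(ds, i5, i3)
    assert set(rep.results) == set(KNOWN_GROUP_FACTORS)
    for factor, per in rep.direction_flags().items():
        assert all(per.values()), factor


# ---------------------------------------------------------------------------
# Age regression
# ---------------------------------------------------------------------------


def test_exact_line_recovered_to_machine_precision(small_survey):
    df = small_survey.frame
    idx = _index_like(small_survey, 1.0674 - 0.0029 * df["age"].astype(float))
    res = age_regression(small_survey, idx, "male")
    assert res.slope == pytest.approx(-0.0029, abs=1e-12)
    assert res.intercept == pytest.approx(1.0674, abs=1e-10)
    assert res.n == int((df["sex"] == "male").sum())


def test_constant_index_gives_zero_slope(small_survey):
    idx = _index_like(small_survey, [0.8] * small_survey.n)
    res = age_regression(small_survey, idx, "female")
    assert res.slope == pytest.approx(0.0, abs=1e-12)


def test_degenerate_designs_rejected(small_survey):
    df = small_survey.frame.copy()
    df["age"] = 44
    ds = SurveyDataset(df, {})
    idx = _index_like(ds, np.linspace(0, 1, ds.n))
    with pytest.raises(ValueError, match="ages"):
        age_regression(ds, idx, "male")
    tiny = SurveyDataset(small_survey.frame.head(2).copy(), {})
    with pytest.raises(ValueError, match="3"):
        age_regression(tiny, idx.head(2), "male")


def test_generating_slope_recovered_within_ci():
    ds = generate_population(GeneratorConfig(n=4000, seed=501))
    idx = index_column(ds, toy_value_set("5L"))
    res = age_regression(ds, idx, "male")
    lo, hi = res.slope_ci
    assert lo <= -0.0029 <= hi


# ---------------------------------------------------------------------------
# Spearman convergent validity
# ---------------------------------------------------------------------------


def spearman_oracle(a, b):
    """Brute-force Spearman: Pearson correlation of average ranks."""

    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        i = 0
        sorted_x = x[order]
        while i < len(x):
            j = i
            while j < len(x) and sorted_x[j] == sorted_x[i]:
                j += 1
            r[order[i:j]] = (i + j + 1) / 2  # average of ranks i+1..j
            i = j
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


def test_variable_against_itself_has_rho_one(small_survey):
    i5 = index_column(small_survey, toy_value_set("5L"))
    rep = convergent_matrix(small_survey, i5)
    df = small_survey.frame
    # mobility 5L vs mobility 3L on a consistent collapse is strongly
    # positive; the diagonal-of-interest sanity check uses the oracle below.
    mask = df["mo5"].notna() & df["mo3"].notna()
    oracle = spearman_oracle(
        df.loc[mask, "mo5"].astype(float), df.loc[mask, "mo3"].astype(float)
    )
    assert rep.rho.loc["mobility", "mobility_3l"] == pytest.approx(oracle, abs=1e-12)


def test_perfect_antimonotone_pair():
    ds = generate_population(GeneratorConfig(n=5, seed=0, missing_rates=(0, 0, 0)))
    df = ds.frame.copy()
    df["mo5"] = pd.array([1, 2, 3, 4, 5], dtype="Int64")
    df["eq_vas"] = pd.array([90, 80, 70, 60, 50], dtype="Int64")
    ds = SurveyDataset(df, {})
    i5 = _index_like(ds, np.linspace(1, 0, 5))
    rep = convergent_matrix(ds, i5)
    assert rep.rho.loc["mobility", "eq_vas"] == pytest.approx(-1.0)


def test_tied_fixture_matches_brute_force_rank_formula():
    ds = generate_population(GeneratorConfig(n=6, seed=0, missing_rates=(0, 0, 0)))
    df = ds.frame.copy()
    a = [1, 2, 2, 3, 3, 3]
    b = [5, 4, 4, 2, 3, 1]
    df["pd5"] = pd.array(a, dtype="Int64")
    df["sf1"] = pd.array(b, dtype="Int64")
    ds = SurveyDataset(df, {})
    rep = convergent_matrix(ds, _index_like(ds, np.linspace(0, 1, 6)))
    assert rep.rho.loc["pain_discomfort", "sf1"] == pytest.approx(
        spearman_oracle(a, b), abs=1e-12
    )


def test_rank_invariance_under_monotone_transform(small_survey):
    i5 = index_column(small_survey, toy_value_set("5L"))
    rep1 = convergent_matrix(small_survey, i5)
    rep2 = convergent_matrix(small_survey, np.exp(3 * i5))
    pd.testing.assert_frame_equal(rep1.rho, rep2.rho, atol=1e-12)


def test_constant_variable_reported_missing_with_warning(small_survey):
    df = small_survey.frame.copy()
    df["sf1"] = pd.array([3] * len(df), dtype="Int64")
    ds = SurveyDataset(df, {})
    i5 = index_column(ds, toy_value_set("5L"))
    with pytest.warns(UserWarning, match="constant"):
        rep = convergent_matrix(ds, i5)
    assert np.isnan(rep.rho.loc["mobility", "sf1"])


def test_sign_conventions_on_synthetic_defaults(medium_survey):
    i5 = index_column(medium_survey, toy_value_set("5L"))
    rep = convergent_matrix(medium_survey, i5)
    for dim in DIMENSIONS:
        assert rep.rho.loc[dim, "eq_vas"] < 0          # worse levels, lower VAS
        assert rep.rho.loc[dim, f"{dim}_3l"] > 0.5     # same-dimension agreement
        assert rep.rho.loc[dim, "sf1"] > 0             # worse levels, worse SF-1
    assert rep.rho.loc["index_5l", "eq_vas"] > 0
    assert rep.rho.loc["index_5l", "sf1"] < 0
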