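"""Data model, survey I/O round-trips, and feasibility accounting."""

import numpy as np
import pandas as pd
import pytest

from eq5dval import (
    Eq5dProfile,
    GeneratorConfig,
    SurveyFormatError,
    age_group_of,
    assess_feasibility,
    generate_population,
    read_survey,
    write_survey,
)
from eq5dval.datamodel import COLS_3L, COLS_5L, REQUIRED_COLUMNS, SurveyDataset

HEADER = ",".join(REQUIRED_COLUMNS)


def _row(id_, **kw):
    base = dict(
        id=id_, age="44", sex="male", education="higher",
        economic_status=">360", diabetes="no",
        mo5="1", sc5="1", ua5="2", pd5="1", ad5="1",
        mo3="1", sc3="1", ua3="2", pd3="1", ad3="1",
        eq_vas="85", sf1="2",
    )
    base.update(kw)
    return ",".join(base[c] for c in REQUIRED_COLUMNS)


def test_well_formed_file_preserves_ids_in_order(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("\n".join([HEADER, _row("a"), _row("b"), _row("c")]))
    ds = read_survey(str(path))
    assert list(ds.frame["id"]) == ["a", "b", "c"]
    assert ds.n == 3


def test_out_of_range_level_rejected_naming_row(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("\n".join([HEADER, _row("a"), _row("b", mo5="6")]))
    with pytest.raises(SurveyFormatError, match="row 2.*mo5"):
        read_survey(str(path))


def test_unknown_category_lists_allowed_labels(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("\n".join([HEADER, _row("a", sex="unknown")]))
    with pytest.raises(SurveyFormatError, match="female"):
        read_survey(str(path))


def test_duplicate_ids_rejected(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("\n".join([HEADER, _row("a"), _row("a")]))
    with pytest.raises(SurveyFormatError, match="duplicate"):
        read_survey(str(path))


def test_round_trip_identity_on_generated_dataset(tmp_path):
    ds = generate_population(GeneratorConfig(n=50, seed=3))
    path = tmp_path / "rt.csv"
    write_survey(ds, str(path))
    back = read_survey(str(path))
    assert back.equals(ds)


def test_tab_delimited_round_trip(tmp_path):
    ds = generate_population(GeneratorConfig(n=20, seed=4))
    path = tmp_path / "rt.tsv"
    write_survey(ds, str(path), sep="\t")
    back = read_survey(str(path))
    assert back.equals(ds)


def test_empty_dataset_writes_header_only(tmp_path):
    ds = generate_population(GeneratorConfig(n=0, seed=0))
    path = tmp_path / "empty.csv"
    write_survey(ds, str(path))
    lines = path.read_text().strip().splitlines()
    assert lines == [HEADER]


def test_missing_vas_encoded_as_single_empty_token(tmp_path):
    ds = generate_population(GeneratorConfig(n=10, seed=5))
    df = ds.frame.copy()
    df.loc[df.index[4], "eq_vas"] = pd.NA
    ds2 = SurveyDataset(df, {})
    path = tmp_path / "m.csv"
    write_survey(ds2, str(path))
    col = [line.split(",")[REQUIRED_COLUMNS.index("eq_vas")]
           for line in path.read_text().strip().splitlines()[1:]]
    assert col.count("") == 1


def test_extra_columns_pass_through(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("\n".join([HEADER + ",note", _row("a") + ",hello"]))
    ds = read_survey(str(path))
    assert list(ds.frame["note"]) == ["hello"]
    out = tmp_path / "o.csv"
    write_survey(ds, str(out))
    assert read_survey(str(out)).frame["note"].tolist() == ["hello"]


# ---------------------------------------------------------------------------
# Feasibility
# ---------------------------------------------------------------------------


def _complete_frame(n):
    ds = generate_population(
        GeneratorConfig(n=n, seed=9, missing_rates=(0.0, 0.0, 0.0))
    )
    return ds


def test_feasibility_zero_when_complete():
    rep = assess_feasibility(_complete_frame(10))
    assert (rep.missing_5l, rep.missing_3l, rep.missing_vas) == (0.0, 0.0, 0.0)


def test_feasibility_counts_records_not_items():
    ds = _complete_frame(1000)
    df = ds.frame.copy()
    for i in range(4):  # four records with a missing 5L item
        df.loc[df.index[i], COLS_5L[i % 5]] = pd.NA
    # one record missing two 3L items still counts once
    df.loc[df.index[10], COLS_3L[0]] = pd.NA
    df.loc[df.index[10], COLS_3L[1]] = pd.NA
    rep = assess_feasibility(SurveyDataset(df, {}))
    assert rep.missing_5l == pytest.approx(0.004)
    assert rep.missing_3l == pytest.approx(0.001)


def test_feasibility_invariant_under_reordering():
    ds = generate_population(GeneratorConfig(n=500, seed=21))
    rep1 = assess_feasibility(ds)
    shuffled = SurveyDataset(
        ds.frame.sample(frac=1.0, random_state=0).reset_index(drop=True), {}
    )
    rep2 = assess_feasibility(shuffled)
    assert rep1 == rep2


def test_feasibility_empty_dataset_errors():
    with pytest.raises(ValueError):
        assess_feasibility(generate_population(GeneratorConfig(n=0, seed=0)))


# ---------------------------------------------------------------------------
# Profiles and age groups
# ---------------------------------------------------------------------------


def test_age_group_agrees_with_exhaustive_lookup():
    for age in range(18, 131):
        if age <= 29:
            expect = "18-29"
        elif age <= 39:
            expect = "30-39"
        elif age <= 49:
            expect = "40-49"
        elif age <= 59:
            expect = "50-59"
        elif age <= 69:
            expect = "60-69"
        else:
            expect = "70+"
        assert age_group_of(age) == expect
    with pytest.raises(ValueError):
        age_group_of(17)


def test_profile_invariants():
    best = Eq5dProfile("5L", 1, 1, 1, 1, 1)
    assert best.is_best and best.complete and best.label == "11111"
    partial = Eq5dProfile("3L", 1, None, 2, 1, 3)
    assert not partial.complete and not partial.is_best
    assert partial.label == "1.213"
    with pytest.raises(ValueError):
        Eq5dProfile("3L", 4, 1, 1, 1, 1)
    with pytest.raises(ValueError):
        Eq5dProfile("5L", 0, 1, 1, 1, 1)


def test_records_iteration_matches_frame(small_survey):
    rec = next(small_survey.records())
    row = small_survey.frame.iloc[0]
    assert rec.id == row["id"]
    assert rec.profile5.mobility == (
        None if pd.isna(row["mo5"]) else int(row["mo5"])
    )
    assert rec.age_group == age_group_of(int(row["age"]))
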