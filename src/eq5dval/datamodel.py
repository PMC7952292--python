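"""Domain model for paired EQ-5D-5L / EQ-5D-3L general-population surveys.

The central in-memory container is :class:`SurveyDataset`, a thin wrapper
around a typed :class:`pandas.DataFrame` with one row per respondent.  Column
names follow the on-disk schema (see :mod:`eq5dval.io`): the five descriptive
dimensions are abbreviated ``mo`` (mobility), ``sc`` (self-care), ``ua``
(usual activities), ``pd`` (pain/discomfort), ``ad`` (anxiety/depression),
suffixed ``5`` or ``3`` for the 5-level and 3-level instruments.

Missing responses are represented with pandas missing values (``pd.NA``);
ordinal columns use the nullable ``Int64`` dtype so missingness never silently
coerces levels to floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Descriptive-system vocabulary
# ---------------------------------------------------------------------------

DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

DIM_ABBR: dict[str, str] = {
    "mobility": "mo",
    "self_care": "sc",
    "usual_activities": "ua",
    "pain_discomfort": "pd",
    "anxiety_depression": "ad",
}

COLS_5L: tuple[str, ...] = tuple(DIM_ABBR[d] + "5" for d in DIMENSIONS)
COLS_3L: tuple[str, ...] = tuple(DIM_ABBR[d] + "3" for d in DIMENSIONS)

SEX_LEVELS: tuple[str, ...] = ("female", "male")

# Six education categories, in the order they are reported for the survey
# sample the generator emulates.
EDUCATION_LEVELS: tuple[str, ...] = (
    "primary",
    "vocational",
    "secondary",
    "post_secondary",
    "higher",
    "other",
)

# Monthly household income per person (EUR bands) plus the two non-response
# categories, which are retained as factor levels rather than missing data.
ECONOMIC_LEVELS: tuple[str, ...] = (
    "<=120",
    "121-180",
    "181-240",
    "241-360",
    ">360",
    "hard_to_say",
    "no_response",
)

AGE_GROUP_LABELS: tuple[str, ...] = ("18-29", "30-39", "40-49", "50-59", "60-69", "70+")
_AGE_GROUP_BOUNDS: tuple[tuple[int, int], ...] = (
    (18, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 130),
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "id",
    "age",
    "sex",
    "education",
    "economic_status",
    "diabetes",
    *COLS_5L,
    *COLS_3L,
    "eq_vas",
    "sf1",
)


class SurveyFormatError(ValueError):
    """A survey table violates the documented schema."""


def age_group_of(age: int) -> str:
    """Return the age-band label containing ``age`` (total on 18..130)."""
    for label, (lo, hi) in zip(AGE_GROUP_LABELS, _AGE_GROUP_BOUNDS):
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside the supported range 18-130")


def age_group_column(age: pd.Series) -> pd.Series:
    """Vectorised :func:`age_group_of` as an ordered categorical."""
    bins = [17, 29, 39, 49, 59, 69, 130]
    return pd.cut(age.astype("float"), bins=bins, labels=AGE_GROUP_LABELS).astype(
        pd.CategoricalDtype(AGE_GROUP_LABELS, ordered=True)
    )


# ---------------------------------------------------------------------------
# Profiles and respondents
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Eq5dProfile:
    """One descriptive-system response: five ordinal items.

    ``version`` is ``"5L"`` (levels 1..5) or ``"3L"`` (levels 1..3); an item
    is ``None`` when missing.
    """

    version: str
    mobility: Optional[int]
    self_care: Optional[int]
    usual_activities: Optional[int]
    pain_discomfort: Optional[int]
    anxiety_depression: Optional[int]

    def __post_init__(self) -> None:
        if self.version not in ("3L", "5L"):
            raise ValueError(f"unknown version {self.version!r}")
        top = 3 if self.version == "3L" else 5
        for dim, lev in zip(DIMENSIONS, self.levels):
            if lev is not None and not (1 <= int(lev) <= top):
                raise ValueError(
                    f"{dim} level {lev} out of range 1..{top} for {self.version}"
                )

    @property
    def levels(self) -> tuple[Optional[int], ...]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @property
    def complete(self) -> bool:
        return all(lev is not None for lev in self.levels)

    @property
    def is_best(self) -> bool:
        """True for the best health state, pattern 11111."""
        return self.complete and all(lev == 1 for lev in self.levels)

    @property
    def label(self) -> str:
        return "".join("." if lev is None else str(lev) for lev in self.levels)


@dataclass(frozen=True)
class RespondentRecord:
    """One survey row: demographics plus the paired profiles."""

    id: str
    age: int
    sex: str
    education: str
    economic_status: str
    diabetes: Optional[bool]
    profile5: Eq5dProfile
    profile3: Eq5dProfile
    eq_vas: Optional[int]
    sf1: Optional[int]

    @property
    def age_group(self) -> str:
        return age_group_of(self.age)


def _opt_int(value) -> Optional[int]:
    return None if pd.isna(value) else int(value)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class SurveyDataset:
    """A survey table plus free-form metadata (source, seed, generator truth)."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_frame(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[RespondentRecord]:
        for _, row in self.frame.iterrows():
            yield RespondentRecord(
                id=str(row["id"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                education=str(row["education"]),
                economic_status=str(row["economic_status"]),
                diabetes=None if pd.isna(row["diabetes"]) else bool(row["diabetes"]),
                profile5=Eq5dProfile("5L", *(_opt_int(row[c]) for c in COLS_5L)),
                profile3=Eq5dProfile("3L", *(_opt_int(row[c]) for c in COLS_3L)),
                eq_vas=_opt_int(row["eq_vas"]),
                sf1=_opt_int(row["sf1"]),
            )

    def equals(self, other: "SurveyDataset") -> bool:
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)


def _check_levels(df: pd.DataFrame, cols: Sequence[str], top: int) -> None:
    for col in cols:
        values = df[col]
        bad = values.notna() & ~values.isin(range(1, top + 1))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SurveyFormatError(
                f"row {row + 1}, column {col!r}: level {values.iloc[row]} "
                f"out of range 1..{top}"
            )


def validate_frame(df: pd.DataFrame) -> None:
    """Enforce the schema invariants, naming the offending row and column."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SurveyFormatError(f"missing required columns: {missing_cols}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise SurveyFormatError(f"duplicate respondent id {dup!r}")
    if df["age"].isna().any():
        row = int(np.flatnonzero(df["age"].isna().to_numpy())[0])
        raise SurveyFormatError(f"row {row + 1}, column 'age': missing age")
    ages = df["age"].astype("float")
    if ((ages < 18) | (ages > 130)).any():
        row = int(np.flatnonzero(((ages < 18) | (ages > 130)).to_numpy())[0])
        raise SurveyFormatError(
            f"row {row + 1}, column 'age': age {df['age'].iloc[row]} outside 18-130"
        )
    for col, allowed in (("sex", SEX_LEVELS), ("education", EDUCATION_LEVELS),
                         ("economic_status", ECONOMIC_LEVELS)):
        vals = df[col]
        bad = vals.notna() & ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SurveyFormatError(
                f"row {row + 1}, column {col!r}: unknown category "
                f"{vals.iloc[row]!r}; allowed: {list(allowed)}"
            )
    _check_levels(df, COLS_5L, 5)
    _check_levels(df, COLS_3L, 3)
    vas = df["eq_vas"]
    bad = vas.notna() & ((vas < 0) | (vas > 100))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SurveyFormatError(
            f"row {row + 1}, column 'eq_vas': value {vas.iloc[row]} outside 0-100"
        )
    sf1 = df["sf1"]
    bad = sf1.notna() & ~sf1.isin(range(1, 6))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SurveyFormatError(
            f"row {row + 1}, column 'sf1': value {sf1.iloc[row]} outside 1-5"
        )


# ---------------------------------------------------------------------------
# Feasibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeasibilityReport:
    """Instrument-level missing-data proportions.

    A record counts as missing for an instrument iff at least one of its
    items is missing; the denominator is always the full sample size.
    """

    missing_5l: float
    missing_3l: float
    missing_vas: float
    n_total: int

    def as_dict(self) -> dict:
        return {
            "missing_5l": self.missing_5l,
            "missing_3l": self.missing_3l,
            "missing_vas": self.missing_vas,
            "n_total": self.n_total,
        }


def assess_feasibility(dataset: SurveyDataset) -> FeasibilityReport:
    """Proportion of respondents with any missing item, per instrument."""
    if dataset.n == 0:
        raise ValueError("feasibility is undefined for an empty dataset")
    df = dataset.frame
    m5 = df[list(COLS_5L)].isna().any(axis=1).mean()
    m3 = df[list(COLS_3L)].isna().any(axis=1).mean()
    mv = df["eq_vas"].isna().mean()
    return FeasibilityReport(float(m5), float(m3), float(mv), dataset.n)
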