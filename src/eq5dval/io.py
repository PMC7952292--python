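"""Delimited-text readers and writers for survey tables.

Files are UTF-8 with a header row.  Comma is the default delimiter; tab is
accepted (auto-detected from the header).  Missing values are encoded as the
empty field.  Columns beyond the documented schema are preserved untouched,
as plain strings, in both directions.
"""

from __future__ import annotations

import io as _io
import os
from typing import Optional, Union

import pandas as pd

from .datamodel import (
    COLS_3L,
    COLS_5L,
    REQUIRED_COLUMNS,
    SurveyDataset,
    SurveyFormatError,
    validate_frame,
)

MISSING_TOKEN = ""

_INT_COLS = ("age", *COLS_5L, *COLS_3L, "eq_vas", "sf1")
_DIABETES_MAP = {"yes": True, "no": False, "1": True, "0": False,
                 "true": True, "false": False}


def _sniff_sep(path: Union[str, os.PathLike]) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_survey(
    path: Union[str, os.PathLike],
    sep: Optional[str] = None,
    metadata: Optional[dict] = None,
) -> SurveyDataset:
    """Read a survey table, enforcing the schema.

    Out-of-range levels and unknown category labels are rejected with an
    error naming the data row (1-based, excluding the header) and column;
    they are never coerced.
    """
    if sep is None:
        sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      na_values=[MISSING_TOKEN], encoding="utf-8")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SurveyFormatError(f"missing required columns: {missing_cols}")

    df = raw.copy()
    for col in _INT_COLS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & parsed.isna()
        if bad.any():
            row = int(bad.to_numpy().nonzero()[0][0])
            raise SurveyFormatError(
                f"row {row + 1}, column {col!r}: cannot parse "
                f"{df[col].iloc[row]!r} as an integer"
            )
        frac = parsed.dropna() % 1
        if (frac != 0).any():
            row = int((parsed % 1 != 0).fillna(False).to_numpy().nonzero()[0][0])
            raise SurveyFormatError(
                f"row {row + 1}, column {col!r}: non-integer value "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = parsed.astype("Int64")

    diab = df["diabetes"].str.strip().str.lower()
    bad = diab.notna() & ~diab.isin(_DIABETES_MAP)
    if bad.any():
        row = int(bad.to_numpy().nonzero()[0][0])
        raise SurveyFormatError(
            f"row {row + 1}, column 'diabetes': {df['diabetes'].iloc[row]!r} "
            f"not one of yes/no"
        )
    df["diabetes"] = diab.map(_DIABETES_MAP).astype("boolean")
    df["id"] = df["id"].astype(str)

    validate_frame(df)
    meta = dict(metadata or {})
    meta.setdefault("source", str(path))
    return SurveyDataset(df, meta)


def write_survey(
    dataset: SurveyDataset,
    path: Union[str, os.PathLike],
    sep: str = ",",
) -> None:
    """Write a survey table losslessly with a stable column order.

    Documented columns come first, in schema order; extra columns follow in
    their original order.  Missing values become the empty field.
    """
    df = dataset.frame.copy()
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df = df[list(REQUIRED_COLUMNS) + extras]
    df["diabetes"] = df["diabetes"].map({True: "yes", False: "no"})
    df.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN, encoding="utf-8")


def survey_to_string(dataset: SurveyDataset, sep: str = ",") -> str:
    buf = _io.StringIO()
    write_survey_buffer(dataset, buf, sep=sep)
    return buf.getvalue()


def write_survey_buffer(dataset: SurveyDataset, buf, sep: str = ",") -> None:
    df = dataset.frame.copy()
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df = df[list(REQUIRED_COLUMNS) + extras]
    df["diabetes"] = df["diabetes"].map({True: "yes", False: "no"})
    df.to_csv(buf, sep=sep, index=False, na_rep=MISSING_TOKEN)
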