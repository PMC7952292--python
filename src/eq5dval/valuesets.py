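"""Additive EQ-5D value sets and index-value (utility) scoring.

A value set maps a complete descriptive-system profile to a single utility:

    index = full_health_value
            - sum of per-(dimension, level) decrements
            - sum of extra-term coefficients whose indicator fires

Level-1 decrements are identically zero, so the best state 11111 scores
``full_health_value`` when no extra term applies.  Utilities below zero are
permitted — published sets contain worse-than-dead states.

Extra terms cover the interaction constants some published sets carry; the
only supported indicator is a threshold ("any dimension at level >= L"),
which is how such constants (e.g. the common "N3" term) are defined.

The on-disk format is delimited text: a ``#`` header block of ``key=value``
lines (version, label, full_health_value, optional ``extra_term`` lines of
the form ``name;min_level=<int>;coef=<float>``) followed by a CSV body with
columns ``dimension,level,decrement``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import COLS_3L, COLS_5L, DIMENSIONS, Eq5dProfile, SurveyDataset


class ValueSetError(ValueError):
    """A value-set file or container is malformed."""


@dataclass(frozen=True)
class ExtraTerm:
    """Threshold indicator term: fires iff any dimension level >= min_level."""

    name: str
    min_level: int
    coefficient: float

    def applies(self, levels: tuple[int, ...]) -> bool:
        return any(lev >= self.min_level for lev in levels)


@dataclass
class ValueSet:
    version: str  # "3L" or "5L"
    label: str
    full_health_value: float = 1.0
    decrements: dict[tuple[str, int], float] = field(default_factory=dict)
    extra_terms: list[ExtraTerm] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return 3 if self.version == "3L" else 5

    def validate(self) -> None:
        if self.version not in ("3L", "5L"):
            raise ValueSetError(f"unknown version {self.version!r}")
        for dim in DIMENSIONS:
            for lev in range(1, self.n_levels + 1):
                if (dim, lev) not in self.decrements:
                    raise ValueSetError(
                        f"value set {self.label!r} lacks a decrement for "
                        f"dimension {dim!r} level {lev}"
                    )
            if abs(self.decrements[(dim, 1)]) > 1e-12:
                raise ValueSetError(f"level-1 decrement for {dim!r} must be 0")
            steps = [self.decrements[(dim, lev)] for lev in range(1, self.n_levels + 1)]
            if any(b < a - 1e-12 for a, b in zip(steps, steps[1:])):
                # Some published sets violate monotonicity; warn, don't fail.
                warnings.warn(
                    f"value set {self.label!r}: decrements not nondecreasing "
                    f"in level for dimension {dim!r}",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class IndexValue:
    value: float
    value_set_label: str


def toy_value_set(version: str = "5L") -> ValueSet:
    """Synthetic fixture set: equal per-level steps, no extra terms.

    5L decrement = 0.05*(level-1) per dimension (55555 -> 0.0); the 3L
    analogue uses steps of 0.10 so 33333 -> 0.0 as well.
    """
    step = 0.05 if version == "5L" else 0.10
    top = 5 if version == "5L" else 3
    dec = {(dim, lev): step * (lev - 1) for dim in DIMENSIONS for lev in range(1, top + 1)}
    vs = ValueSet(version=version, label=f"toy-{version}", full_health_value=1.0,
                  decrements=dec)
    vs.validate()
    return vs


def compute_index(profile: Eq5dProfile, vs: ValueSet) -> IndexValue:
    """Score a complete profile under a value set.

    Raises on incomplete profiles: exclusion policy belongs to the caller.
    """
    if profile.version != vs.version:
        raise ValueSetError(
            f"profile version {profile.version} != value set version {vs.version}"
        )
    if not profile.complete:
        raise ValueSetError("cannot score an incomplete profile")
    levels = tuple(int(lev) for lev in profile.levels)
    value = vs.full_health_value
    value -= sum(vs.decrements[(dim, lev)] for dim, lev in zip(DIMENSIONS, levels))
    value -= sum(t.coefficient for t in vs.extra_terms if t.applies(levels))
    return IndexValue(float(value), vs.label)


def index_column(dataset: SurveyDataset, vs: ValueSet) -> pd.Series:
    """Vectorised index values aligned to records; NaN where incomplete."""
    cols = COLS_5L if vs.version == "5L" else COLS_3L
    df = dataset.frame
    complete = df[list(cols)].notna().all(axis=1)
    total = np.full(len(df), np.nan)
    levels = df.loc[complete, list(cols)].astype(int).to_numpy()
    dec = np.zeros(len(levels))
    for j, dim in enumerate(DIMENSIONS):
        lut = np.array([vs.decrements[(dim, lev)] for lev in range(1, vs.n_levels + 1)])
        dec += lut[levels[:, j] - 1]
    value = vs.full_health_value - dec
    for term in vs.extra_terms:
        fires = (levels >= term.min_level).any(axis=1)
        value = value - term.coefficient * fires
    total[complete.to_numpy()] = value
    return pd.Series(total, index=df.index, name=f"index_{vs.version.lower()}")


# ---------------------------------------------------------------------------
# File format
# ---------------------------------------------------------------------------


def save_value_set(vs: ValueSet, path: Union[str, os.PathLike]) -> None:
    vs.validate()
    lines = [
        f"# version={vs.version}",
        f"# label={vs.label}",
        f"# full_health_value={vs.full_health_value!r}",
    ]
    for t in vs.extra_terms:
        lines.append(f"# extra_term={t.name};min_level={t.min_level};coef={t.coefficient!r}")
    lines.append("dimension,level,decrement")
    for dim in DIMENSIONS:
        for lev in range(1, vs.n_levels + 1):
            lines.append(f"{dim},{lev},{vs.decrements[(dim, lev)]!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_extra_term(value: str) -> ExtraTerm:
    parts = value.split(";")
    if len(parts) != 3:
        raise ValueSetError(f"malformed extra_term {value!r}")
    name = parts[0]
    kv = dict(p.split("=", 1) for p in parts[1:])
    try:
        return ExtraTerm(name, int(kv["min_level"]), float(kv["coef"]))
    except (KeyError, ValueError) as exc:
        raise ValueSetError(f"malformed extra_term {value!r}") from exc


def load_value_set(path: Union[str, os.PathLike]) -> ValueSet:
    header: dict[str, str] = {}
    extra_terms: list[ExtraTerm] = []
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                content = line.lstrip("#").strip()
                if "=" not in content:
                    raise ValueSetError(f"malformed header line {line!r}")
                key, value = content.split("=", 1)
                key, value = key.strip(), value.strip()
                if key == "extra_term":
                    extra_terms.append(_parse_extra_term(value))
                else:
                    header[key] = value
            else:
                body_lines.append(line)

    for key in ("version", "label"):
        if key not in header:
            raise ValueSetError(f"value-set file lacks header key {key!r}")
    version = header["version"]
    fh_value = float(header.get("full_health_value", 1.0))

    if not body_lines or body_lines[0].split(",")[:3] != ["dimension", "level", "decrement"]:
        raise ValueSetError("value-set body must start with 'dimension,level,decrement'")
    decrements: dict[tuple[str, int], float] = {}
    for i, line in enumerate(body_lines[1:], start=1):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise ValueSetError(f"body row {i}: expected 3 fields, got {len(parts)}")
        dim, lev_s, dec_s = parts
        if dim not in DIMENSIONS:
            raise ValueSetError(f"body row {i}: unknown dimension {dim!r}")
        try:
            lev, dec = int(lev_s), float(dec_s)
        except ValueError as exc:
            raise ValueSetError(f"body row {i}: malformed numbers") from exc
        top = 3 if version == "3L" else 5
        if not 1 <= lev <= top:
            raise ValueSetError(
                f"body row {i}: level {lev} out of range for version {version}"
            )
        if (dim, lev) in decrements:
            raise ValueSetError(f"body row {i}: duplicate cell ({dim}, {lev})")
        decrements[(dim, lev)] = dec

    vs = ValueSet(version=version, label=header["label"],
                  full_health_value=fh_value, decrements=decrements,
                  extra_terms=extra_terms)
    vs.validate()
    return vs
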