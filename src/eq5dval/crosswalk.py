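"""Redistribution tables, response inconsistency, and ceiling effects for
paired 3L/5L descriptive-system responses.

Consistency of a (3L, 5L) pair follows the Janssen scheme: 3L level 1 may
map to 5L {1,2}, 3L level 2 to 5L {2,3,4}, and 3L level 3 to 5L {4,5}; the
remaining 8 of the 15 possible pairs are inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import COLS_3L, COLS_5L, DIMENSIONS, SurveyDataset

CONSISTENT_PAIRS: frozenset[tuple[int, int]] = frozenset(
    {(1, 1), (1, 2), (2, 2), (2, 3), (2, 4), (3, 4), (3, 5)}
)


def classify_pair(level3: int, level5: int) -> str:
    """Classify a (3L, 5L) response pair as 'consistent' or 'inconsistent'."""
    if level3 not in (1, 2, 3):
        raise ValueError(f"3L level {level3} out of range 1..3")
    if level5 not in (1, 2, 3, 4, 5):
        raise ValueError(f"5L level {level5} out of range 1..5")
    return "consistent" if (level3, level5) in CONSISTENT_PAIRS else "inconsistent"


# ---------------------------------------------------------------------------
# Redistribution
# ---------------------------------------------------------------------------


@dataclass
class DimensionRedistribution:
    """Pair table for one dimension, over records with both items non-missing.

    ``consistent_pct`` is conditional on consistent pairs within each 3L
    level, so each 3L level block sums to 100; inconsistent pairs are
    reported separately as a single per-dimension percentage.
    """

    dimension: str
    counts: pd.DataFrame  # 3 rows (3L level) x 5 cols (5L level)
    n_pairs: int
    inconsistency_pct: float
    consistent_pct: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class RedistributionReport:
    dimensions: dict[str, DimensionRedistribution]
    mean_inconsistency_pct: float

    def inconsistency_by_dimension(self) -> dict[str, float]:
        return {d: r.inconsistency_pct for d, r in self.dimensions.items()}


def redistribution(dataset: SurveyDataset) -> RedistributionReport:
    """Cross-tabulate paired 3L/5L responses per dimension.

    Uses complete pairs only (both items non-missing).  The per-dimension
    inconsistency is the percentage of pairs outside the consistency scheme;
    the report mean is the unweighted arithmetic mean of the five dimensions.
    """
    df = dataset.frame
    dims: dict[str, DimensionRedistribution] = {}
    for dim, c3, c5 in zip(DIMENSIONS, COLS_3L, COLS_5L):
        mask = df[c3].notna() & df[c5].notna()
        n_pairs = int(mask.sum())
        if n_pairs == 0:
            raise ValueError(f"dimension {dim!r} has no complete 3L/5L pairs")
        l3 = df.loc[mask, c3].astype(int).to_numpy()
        l5 = df.loc[mask, c5].astype(int).to_numpy()
        counts = np.zeros((3, 5), dtype=int)
        np.add.at(counts, (l3 - 1, l5 - 1), 1)
        table = pd.DataFrame(counts, index=[1, 2, 3], columns=[1, 2, 3, 4, 5])

        n_inconsistent = sum(
            counts[a - 1, b - 1]
            for a in (1, 2, 3)
            for b in (1, 2, 3, 4, 5)
            if (a, b) not in CONSISTENT_PAIRS
        )
        pct: dict[tuple[int, int], float] = {}
        for a in (1, 2, 3):
            denom = sum(counts[a - 1, b - 1] for b in (1, 2, 3, 4, 5)
                        if (a, b) in CONSISTENT_PAIRS)
            for b in (1, 2, 3, 4, 5):
                if (a, b) in CONSISTENT_PAIRS:
                    pct[(a, b)] = (
                        100.0 * counts[a - 1, b - 1] / denom if denom else float("nan")
                    )
        dims[dim] = DimensionRedistribution(
            dimension=dim,
            counts=table,
            n_pairs=n_pairs,
            inconsistency_pct=100.0 * n_inconsistent / n_pairs,
            consistent_pct=pct,
        )
    mean_pct = float(np.mean([r.inconsistency_pct for r in dims.values()]))
    return RedistributionReport(dims, mean_pct)


# ---------------------------------------------------------------------------
# Ceiling effect
# ---------------------------------------------------------------------------


@dataclass
class CeilingReport:
    """Percent of respondents at the best response, per dimension and for the
    full profile (state 11111), with the 3L-5L contrast.

    Per-dimension rows use all non-missing items of that dimension; the
    profile row uses complete profiles.  ``change`` is ceiling_3l -
    ceiling_5l in percentage points at full precision.
    """

    table: pd.DataFrame  # columns: ceiling_3l, ceiling_5l, change, chi2_p, n_3l, n_5l
    method: str = "chi2"


def _compare_proportions(k3: int, n3: int, k5: int, n5: int, method: str) -> float:
    """Two-sided p-value comparing the two at-ceiling proportions."""
    table = np.array([[k3, n3 - k3], [k5, n5 - k5]])
    if method == "chi2":
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            return float("nan")
        res = stats.chi2_contingency(table, correction=False)
        return float(res.pvalue)
    if method == "mcnemar":
        # Proper paired test on discordant counts; approximated from the
        # marginal counts when per-record pairing is unavailable is not
        # meaningful, so this is computed by the caller from paired data.
        raise ValueError("mcnemar requires paired per-record data; use ceiling()")
    raise ValueError(f"unknown method {method!r}")


def ceiling(dataset: SurveyDataset, method: str = "chi2") -> CeilingReport:
    """Ceiling-effect comparison between the 3L and 5L instruments.

    ``method='chi2'`` treats the paired samples as two independent
    proportions (Pearson chi-square without continuity correction);
    ``method='mcnemar'`` runs the statistically proper paired test on the
    discordant cells (exact binomial form).
    """
    df = dataset.frame
    rows = []
    for dim, c3, c5 in zip(DIMENSIONS, COLS_3L, COLS_5L):
        m3, m5 = df[c3].notna(), df[c5].notna()
        n3, n5 = int(m3.sum()), int(m5.sum())
        if n3 == 0 or n5 == 0:
            raise ValueError(f"dimension {dim!r} has an empty denominator")
        k3 = int((df.loc[m3, c3] == 1).sum())
        k5 = int((df.loc[m5, c5] == 1).sum())
        rows.append((dim, k3, n3, k5, n5, m3 & m5, df[c3] == 1, df[c5] == 1))

    complete3 = df[list(COLS_3L)].notna().all(axis=1)
    complete5 = df[list(COLS_5L)].notna().all(axis=1)
    n3p, n5p = int(complete3.sum()), int(complete5.sum())
    if n3p == 0 or n5p == 0:
        raise ValueError("no complete profiles for at least one instrument")
    best3 = complete3 & (df[list(COLS_3L)] == 1).all(axis=1)
    best5 = complete5 & (df[list(COLS_5L)] == 1).all(axis=1)
    rows.append(("health_state_11111", int(best3.sum()), n3p, int(best5.sum()), n5p,
                 complete3 & complete5, best3, best5))

    out = []
    for name, k3, n3, k5, n5, paired_mask, at3, at5 in rows:
        c3pct = 100.0 * k3 / n3
        c5pct = 100.0 * k5 / n5
        if method == "chi2":
            p = _compare_proportions(k3, n3, k5, n5, "chi2")
        else:  # mcnemar on paired records
            both = paired_mask
            b = int((at3[both] & ~at5[both]).sum())
            c = int((~at3[both] & at5[both]).sum())
            if b + c == 0:
                p = float("nan")
            else:
                p = float(stats.binomtest(b, b + c, 0.5).pvalue)
        out.append({"ceiling_3l": c3pct, "ceiling_5l": c5pct,
                    "change": c3pct - c5pct, "chi2_p": p,
                    "n_3l": n3, "n_5l": n5})
    table = pd.DataFrame(out, index=[r[0] for r in rows])
    return CeilingReport(table, method=method)
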