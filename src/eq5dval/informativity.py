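"""Shannon informativity of descriptive-system items.

The Shannon index of an L-level item with level proportions p_i = n_i/N is

    H' = - sum_i p_i log2 p_i                     (0 * log2 0 := 0)

with analytic (delta-method) variance

    var H' = [ sum_i p_i (log2 p_i)^2 - (sum_i p_i log2 p_i)^2 ] / N

and a symmetric normal-approximation 95% CI, H' +/- 1.96 sqrt(var H').
H' ranges from 0 (all mass on one level) to H'max = log2 L; the Shannon
evenness index J' = H'/H'max rescales it to [0, 1] so 3-level and 5-level
items are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import COLS_3L, COLS_5L, DIMENSIONS, SurveyDataset

Z95 = 1.96


@dataclass(frozen=True)
class ShannonResult:
    H: float          # bits
    var_H: float      # bits^2
    ci_low: float
    ci_high: float
    H_max: float      # log2 L, bits
    J: float          # evenness, dimensionless in [0, 1]
    L: int
    N: int
    p: tuple[float, ...]


def shannon(counts, L: int) -> ShannonResult:
    """Shannon index, analytic variance, 95% CI and evenness for level counts."""
    if L < 2:
        raise ValueError("need at least 2 levels")
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (L,):
        raise ValueError(f"expected {L} level counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    N = counts.sum()
    if N < 1:
        raise ValueError("need at least one observation")
    p = counts / N
    nz = p > 0
    logp = np.zeros_like(p)
    logp[nz] = np.log2(p[nz])
    H = float(-(p * logp).sum())
    var_H = float(((p * logp**2).sum() - (p * logp).sum() ** 2) / N)
    var_H = max(var_H, 0.0)  # guard tiny negative rounding
    half = Z95 * np.sqrt(var_H)
    H_max = float(np.log2(L))
    return ShannonResult(
        H=H, var_H=var_H, ci_low=H - half, ci_high=H + half,
        H_max=H_max, J=H / H_max, L=L, N=int(N), p=tuple(p),
    )


def pct_change_J(j_3l: float, j_5l: float) -> float:
    """Percent change in evenness from the 3L to the 5L instrument."""
    if j_3l <= 0:
        raise ValueError("pct change undefined when J'(3L) is 0")
    return 100.0 * (j_5l - j_3l) / j_3l


@dataclass
class InformativityReport:
    """Per-dimension Shannon results for both instruments.

    ``pct_change`` holds the 3L->5L percent change in J'; NaN (with a
    warning at build time) where J'(3L) is zero.  ``rounded_change`` records
    whether the change was computed from 3-decimal display-rounded J'
    values (the arithmetic some printed tables use) or full precision.
    """

    per_dimension: dict[str, dict[str, ShannonResult]]
    pct_change: dict[str, float]
    rounded_change: bool = False


def informativity_report(
    dataset: SurveyDataset, rounded_change: bool = False
) -> InformativityReport:
    """Shannon informativity per dimension and instrument, from non-missing
    responses, plus the relative (evenness) change from 3L to 5L."""
    df = dataset.frame
    per_dim: dict[str, dict[str, ShannonResult]] = {}
    change: dict[str, float] = {}
    for dim, c3, c5 in zip(DIMENSIONS, COLS_3L, COLS_5L):
        results = {}
        for label, col, L in (("3L", c3, 3), ("5L", c5, 5)):
            values = df[col].dropna().astype(int)
            if len(values) == 0:
                raise ValueError(f"dimension {dim!r} has no responses on {label}")
            counts = np.bincount(values.to_numpy(), minlength=L + 1)[1:]
            results[label] = shannon(counts, L)
        per_dim[dim] = results
        j3, j5 = results["3L"].J, results["5L"].J
        if rounded_change:
            j3, j5 = round(j3, 3), round(j5, 3)
        if j3 <= 0:
            warnings.warn(
                f"dimension {dim!r}: J'(3L) = 0, percent change undefined",
                stacklevel=2,
            )
            change[dim] = float("nan")
        else:
            change[dim] = pct_change_J(j3, j5)
    return InformativityReport(per_dim, change, rounded_change)
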