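"""Known-groups and convergent validity.

Known-groups validation asks whether the index value separates groups that
are expected a priori to differ: older respondents, women, respondents with
diabetes, and respondents with worse self-rated health (SF-1) should all
score lower on average.  Each factor is tested with a one-way ANOVA per
instrument (listwise deletion within the analysis cell); the directional
hypotheses are evaluated on group means, not as one-sided tests.

Convergent validity is a matrix of Spearman rank correlations (average-rank
ties, pairwise-complete deletion per cell) between each 5L dimension (and
the 5L index) and EQ VAS, the corresponding 3L dimensions and SF-1.  Signs
follow each variable's natural orientation: dimension levels and SF-1
increase with worse health, EQ VAS and the index increase with better
health, so dimension-vs-VAS cells are negative and index-vs-VAS positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import (
    AGE_GROUP_LABELS,
    COLS_3L,
    DIMENSIONS,
    SurveyDataset,
    age_group_column,
)


# ---------------------------------------------------------------------------
# Known-groups (ANOVA)
# ---------------------------------------------------------------------------


@dataclass
class FactorAnova:
    factor: str
    instrument: str
    groups: list
    means: list[float]
    sizes: list[int]
    F: float
    p: float
    direction_ok: bool


@dataclass
class KnownGroupsReport:
    results: dict[str, dict[str, FactorAnova]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def direction_flags(self) -> dict[str, dict[str, bool]]:
        return {
            factor: {instr: fa.direction_ok for instr, fa in per.items()}
            for factor, per in self.results.items()
        }


def _factor_series(dataset: SurveyDataset, factor: str) -> pd.Series:
    df = dataset.frame
    if factor == "age_group":
        return age_group_column(df["age"])
    if factor == "sex":
        return df["sex"]
    if factor == "diabetes":
        return df["diabetes"].map({True: "yes", False: "no"})
    if factor == "sf1":
        return df["sf1"]
    raise ValueError(f"unknown factor {factor!r}")


def _direction_ok(factor: str, groups: list, means: list[float]) -> bool:
    """Lower mean index expected for the a-priori worse-off group."""
    lookup = dict(zip([str(g) for g in groups], means))
    try:
        if factor == "age_group":
            return lookup["70+"] < lookup["18-29"]
        if factor == "sex":
            return lookup["female"] < lookup["male"]
        if factor == "diabetes":
            return lookup["yes"] < lookup["no"]
        if factor == "sf1":
            return lookup["5"] < lookup["1"]
    except KeyError:
        return False
    raise ValueError(factor)


KNOWN_GROUP_FACTORS = ("age_group", "sex", "diabetes", "sf1")


def known_groups(
    dataset: SurveyDataset, index5: pd.Series, index3: pd.Series
) -> KnownGroupsReport:
    """One-way ANOVA of the index values over each known-group factor."""
    report = KnownGroupsReport()
    for factor in KNOWN_GROUP_FACTORS:
        fvals = _factor_series(dataset, factor)
        per_instrument: dict[str, FactorAnova] = {}
        for instrument, index in (("5L", index5), ("3L", index3)):
            mask = fvals.notna() & index.notna()
            sub_f = fvals[mask].astype(str)
            sub_y = index[mask].astype(float)
            groups = [g for g in sub_f.unique()]
            # stable, meaningful ordering
            if factor == "age_group":
                groups = [g for g in AGE_GROUP_LABELS if g in groups]
            elif factor == "sf1":
                groups = sorted(groups, key=int)
            else:
                groups = sorted(groups)
            samples = [sub_y[sub_f == g].to_numpy() for g in groups]
            if len([s for s in samples if len(s) > 0]) < 2:
                report.skipped[f"{factor}/{instrument}"] = "fewer than 2 non-empty groups"
                warnings.warn(
                    f"known-groups factor {factor!r} skipped for {instrument}: "
                    f"fewer than 2 non-empty groups",
                    stacklevel=2,
                )
                continue
            if all(np.ptp(s) == 0 for s in samples) and np.ptp(sub_y.to_numpy()) == 0:
                F, p = 0.0, 1.0  # identical values within and between
            else:
                F, p = stats.f_oneway(*samples)
            means = [float(np.mean(s)) for s in samples]
            per_instrument[instrument] = FactorAnova(
                factor=factor,
                instrument=instrument,
                groups=groups,
                means=means,
                sizes=[int(len(s)) for s in samples],
                F=float(F),
                p=float(p),
                direction_ok=_direction_ok(factor, groups, means),
            )
        if per_instrument:
            report.results[factor] = per_instrument
    return report


# ---------------------------------------------------------------------------
# Age regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    sex: str
    slope: float          # utility per year of age
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci: tuple[float, float]  # 95%
    n: int


def age_regression(
    dataset: SurveyDataset, index: pd.Series, sex: str
) -> RegressionResult:
    """OLS of the index value on age, for one sex."""
    df = dataset.frame
    mask = (df["sex"] == sex) & index.notna() & df["age"].notna()
    y = index[mask].astype(float).to_numpy()
    x = df.loc[mask, "age"].astype(float).to_numpy()
    if len(y) < 3:
        raise ValueError(f"need at least 3 complete (age, index) pairs for {sex!r}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all ages equal")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        sex=sex,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n=int(len(y)),
    )


# ---------------------------------------------------------------------------
# Convergent validity (Spearman)
# ---------------------------------------------------------------------------


@dataclass
class ConvergentReport:
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    orientation_note: str = (
        "dimension levels and SF-1 increase with worse health; "
        "EQ VAS and index values increase with better health"
    )


def convergent_matrix(dataset: SurveyDataset, index5: pd.Series) -> ConvergentReport:
    """Spearman correlations of each 5L dimension (and the 5L index) with
    EQ VAS, every 3L dimension, and SF-1, with pairwise-complete deletion."""
    df = dataset.frame
    row_vars: dict[str, pd.Series] = {
        dim: df[abbr] for dim, abbr in zip(DIMENSIONS, _cols5())
    }
    row_vars["index_5l"] = index5
    col_vars: dict[str, pd.Series] = {"eq_vas": df["eq_vas"]}
    for dim, c3 in zip(DIMENSIONS, COLS_3L):
        col_vars[f"{dim}_3l"] = df[c3]
    col_vars["sf1"] = df["sf1"]

    rho = pd.DataFrame(index=list(row_vars), columns=list(col_vars), dtype=float)
    pval = rho.copy()
    ncell = pd.DataFrame(index=list(row_vars), columns=list(col_vars), dtype=int)
    for rname, rv in row_vars.items():
        for cname, cv in col_vars.items():
            mask = rv.notna() & cv.notna()
            n = int(mask.sum())
            ncell.loc[rname, cname] = n
            if n < 3:
                rho.loc[rname, cname] = np.nan
                pval.loc[rname, cname] = np.nan
                continue
            a = rv[mask].astype(float).to_numpy()
            b = cv[mask].astype(float).to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"convergent cell ({rname}, {cname}): constant variable, "
                    f"rho undefined",
                    stacklevel=2,
                )
                rho.loc[rname, cname] = np.nan
                pval.loc[rname, cname] = np.nan
                continue
            r, p = stats.spearmanr(a, b)
            rho.loc[rname, cname] = float(r)
            pval.loc[rname, cname] = float(p)
    return ConvergentReport(rho, pval, ncell)


def _cols5() -> tuple[str, ...]:
    from .datamodel import COLS_5L

    return COLS_5L
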