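"""Model-based construct validity via a random-forest "theoretical model".

The procedure builds a reference ("theoretical") prediction of the 5L index
value from five socio-demographic inputs — age group, sex, education,
economic status, diabetes — using a bagged ensemble of regression trees,
then judges construct validity by how closely the held-out prediction-error
distribution matches the model's own internal error distribution:

1. score the survey with a value set and keep complete cases on the five
   predictors plus the index;
2. split uniformly at random into a training fraction (default 60%) and a
   held-out test set (40%);
3. fit a random forest (default 300 trees) on the training set;
4. collect per-observation absolute prediction errors on the training set
   ("internal" errors, resubstitution) and on the test set ("validation"
   errors), plus RMSE for both;
5. report the empirical 95th percentile of the internal errors and the
   percentage of validation errors at or below it ("coverage").

If the questionnaire result agrees with the theory encoded by the model,
the two error distributions overlap and coverage sits near 95%; a genuine
misfit confined to new data drives coverage down.  No p-value is produced —
the comparison is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datamodel import (
    AGE_GROUP_LABELS,
    ECONOMIC_LEVELS,
    EDUCATION_LEVELS,
    SurveyDataset,
    age_group_column,
)
from .valuesets import ValueSet, index_column

PREDICTORS = ("age_group", "sex", "education", "economic_status", "diabetes")


@dataclass
class TheoreticalModelSpec:
    """Hyperparameters of the theoretical model and the split.

    Tree settings beyond the ensemble size follow the scikit-learn
    regression-forest defaults (fully grown trees, ``min_samples_leaf=1``,
    bootstrap resampling).
    """

    predictors: tuple = PREDICTORS
    n_trees: int = 300
    train_fraction: float = 0.60
    seed: int = 0
    min_samples_leaf: int = 1
    max_depth: int | None = None

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")


@dataclass
class ConstructValidityResult:
    rmse_int: float
    rmse_val: float
    errors_int: np.ndarray  # absolute errors, training set
    errors_val: np.ndarray  # absolute errors, held-out set
    q95_int: float
    coverage: float  # percent of errors_val at or below q95_int
    n_train: int
    n_test: int
    spec: TheoreticalModelSpec = field(repr=False, default=None)


# Fixed integer encoding of the categorical predictors.  Tree splits depend
# on the coding, so it is part of the documented procedure: each category is
# mapped to its position in the canonical level order.
_CODES = {
    "age_group": {g: i for i, g in enumerate(AGE_GROUP_LABELS)},
    "sex": {"female": 0, "male": 1},
    "education": {g: i for i, g in enumerate(EDUCATION_LEVELS)},
    "economic_status": {g: i for i, g in enumerate(ECONOMIC_LEVELS)},
    "diabetes": {False: 0, True: 1},
}


def predictor_frame(dataset: SurveyDataset) -> pd.DataFrame:
    """The five predictors as level-coded integers (NaN where missing)."""
    df = dataset.frame
    out = pd.DataFrame(index=df.index)
    out["age_group"] = age_group_column(df["age"]).astype(object).map(
        _CODES["age_group"]
    )
    out["sex"] = df["sex"].map(_CODES["sex"])
    out["education"] = df["education"].map(_CODES["education"])
    out["economic_status"] = df["economic_status"].map(_CODES["economic_status"])
    out["diabetes"] = df["diabetes"].astype(object).map(_CODES["diabetes"])
    return out.astype(float)


def split_train_test(
    n_complete: int, spec: TheoreticalModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform split of ``range(n_complete)``: disjoint, exhaustive."""
    spec.validate()
    if n_complete < 10:
        raise ValueError(f"need at least 10 complete cases, got {n_complete}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_complete)
    n_train = int(round(spec.train_fraction * n_complete))
    n_train = min(max(n_train, 1), n_complete - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def fit_theoretical_model(
    X_train: np.ndarray, y_train: np.ndarray, spec: TheoreticalModelSpec
) -> RandomForestRegressor:
    """Bagged regression-tree ensemble; prediction = mean over trees."""
    spec.validate()
    if len(y_train) == 0:
        raise ValueError("empty training set")
    model = RandomForestRegressor(
        n_estimators=spec.n_trees,
        min_samples_leaf=spec.min_samples_leaf,
        max_depth=spec.max_depth,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    return model


def _oob_predictions(
    model: RandomForestRegressor, X: np.ndarray, n: int
) -> np.ndarray:
    """Out-of-bag predictions on the training set (strict internal errors)."""
    preds = np.zeros(n)
    counts = np.zeros(n)
    n_samples_bootstrap = n
    for est in model.estimators_:
        rng = np.random.RandomState(est.random_state)
        sampled = rng.randint(0, n, n_samples_bootstrap)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        if mask.any():
            preds[mask] += est.predict(X[mask])
            counts[mask] += 1
    if (counts == 0).any():
        # fall back to ensemble prediction for never-left-out points
        full = model.predict(X)
        preds[counts == 0] = full[counts == 0]
        counts[counts == 0] = 1
    return preds / counts


def construct_validity(
    dataset: SurveyDataset,
    vs: ValueSet,
    spec: TheoreticalModelSpec,
    internal: str = "resubstitution",
    holdout_shift: float = 0.0,
) -> ConstructValidityResult:
    """Run the full construct-validity pipeline on a scored survey.

    ``internal`` selects how the model's own error distribution is measured:
    ``"resubstitution"`` (training-set predictions vs observed, the default)
    or ``"oob"`` (out-of-bag, a methodologically stricter option).
    ``holdout_shift`` adds a constant to the *observed* held-out index
    values only — a misspecification probe used in sensitivity checks.
    """
    if internal not in ("resubstitution", "oob"):
        raise ValueError(f"unknown internal-error mode {internal!r}")
    spec.validate()
    index = index_column(dataset, vs)
    X_all = predictor_frame(dataset)
    complete = X_all.notna().all(axis=1) & index.notna()
    X = X_all[complete].to_numpy()
    y = index[complete].astype(float).to_numpy()

    train_idx, test_idx = split_train_test(int(complete.sum()), spec)
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx] + holdout_shift

    model = fit_theoretical_model(X_train, y_train, spec)
    if internal == "oob":
        pred_int = _oob_predictions(model, X_train, len(y_train))
    else:
        pred_int = model.predict(X_train)
    pred_val = model.predict(X_test)

    errors_int = np.abs(y_train - pred_int)
    errors_val = np.abs(y_test - pred_val)
    rmse_int = float(np.sqrt(np.mean((y_train - pred_int) ** 2)))
    rmse_val = float(np.sqrt(np.mean((y_test - pred_val) ** 2)))
    # Linear-interpolation empirical quantile; ties between validation errors
    # and the quantile count as covered (matters only for atoms at zero).
    q95 = float(np.quantile(errors_int, 0.95, method="linear"))
    coverage = float(100.0 * np.mean(errors_val <= q95))
    return ConstructValidityResult(
        rmse_int=rmse_int,
        rmse_val=rmse_val,
        errors_int=errors_int,
        errors_val=errors_val,
        q95_int=q95,
        coverage=coverage,
        n_train=int(len(y_train)),
        n_test=int(len(y_test)),
        spec=spec,
    )
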