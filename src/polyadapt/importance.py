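"""Random-forest parameter importance for simulation summary statistics.

A forest of regression trees (100 by default) is trained to predict each
summary statistic (or each genetic-architecture cell) from the simulation
input parameters; impurity-based feature importances, normalized to sum to 1,
quantify how much each input parameter drives the statistic.  Prediction
accuracy is reported as 10-fold cross-validated R^2 on pooled out-of-fold
predictions together with the range-normalized root-mean-square deviation
(NRMSD), which stays informative for targets whose values concentrate near
zero where R^2 is misleading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = ["DEFAULT_FEATURES", "ImportanceResult", "nrmsd", "fit_importance",
           "cross_validate", "architecture_importance"]

DEFAULT_FEATURES = ("sigma_m", "v_s", "psi", "bottleneck_fraction", "final_multiple")


@dataclass
class ImportanceResult:
    """Relative feature importances and cross-validated accuracy for one
    target statistic."""

    target: str
    features: tuple
    importances: pd.Series  # indexed by feature, sums to 1
    cv_r2: float
    nrmsd: float
    n_rows: int


def nrmsd(y_true, y_pred) -> float:
    """Root-mean-square deviation normalized by the observed target range."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rng = y_true.max() - y_true.min()
    if rng == 0:
        raise ValueError("target has zero range")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)) / rng)


def _prepare(table: pd.DataFrame, target: str, features) -> tuple:
    features = tuple(features)
    cols = list(features) + [target]
    data = table[cols].dropna()
    x = data[list(features)].to_numpy(dtype=float)
    y = data[target].to_numpy(dtype=float)
    if np.all(y == y[0] if y.size else True):
        raise ValueError(f"target {target!r} is constant")
    return x, y, features


def _forest(n_trees: int, seed) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)


def cross_validate(table: pd.DataFrame, target: str,
                   features=DEFAULT_FEATURES, folds: int = 10, seed: int = 0,
                   n_trees: int = 100) -> tuple[float, float]:
    """10-fold cross-validation of the forest: the model is refit on each
    training split and out-of-fold predictions are pooled before computing
    R^2 and NRMSD."""
    x, y, features = _prepare(table, target, features)
    if len(y) < folds:
        raise ValueError("fewer rows than folds")
    pred = np.empty_like(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(x):
        model = _forest(n_trees, seed)
        model.fit(x[train], y[train])
        pred[test] = model.predict(x[test])
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - ss_res / ss_tot)
    return r2, nrmsd(y, pred)


def fit_importance(table: pd.DataFrame, target: str,
                   features=DEFAULT_FEATURES, n_trees: int = 100,
                   seed: int = 0, folds: int = 10) -> ImportanceResult:
    """Fit the forest on the full table for importances, with accuracy from
    10-fold cross-validation.  Deterministic given (table, seed)."""
    x, y, features = _prepare(table, target, features)
    model = _forest(n_trees, seed)
    model.fit(x, y)
    imp = model.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)
    cv_r2, score_nrmsd = cross_validate(table, target, features, folds=folds,
                                        seed=seed, n_trees=n_trees)
    return ImportanceResult(
        target=target,
        features=features,
        importances=pd.Series(imp, index=list(features)),
        cv_r2=cv_r2,
        nrmsd=score_nrmsd,
        n_rows=len(y),
    )


def architecture_importance(cell_table: pd.DataFrame,
                            features=DEFAULT_FEATURES, n_trees: int = 100,
                            seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Parameter importance for the genetic architecture.

    ``cell_table`` holds one row per parameter set with the feature columns
    plus one column per architecture-matrix cell (any column not named in
    ``features``).  Each cell frequency is predicted from the features by its
    own forest; per-cell importances are averaged and renormalized into the
    aggregate importance.  Constant cells (often empty bins) carry no
    information and are skipped.
    """
    features = tuple(features)
    cell_cols = [c for c in cell_table.columns if c not in features]
    if not cell_cols:
        raise ValueError("no architecture cell columns found")
    x = cell_table[list(features)].to_numpy(dtype=float)
    rows = []
    for col in cell_cols:
        y = cell_table[col].to_numpy(dtype=float)
        if np.all(y == y[0]):
            continue
        model = _forest(n_trees, seed)
        model.fit(x, y)
        imp = model.feature_importances_
        total = imp.sum()
        if total > 0:
            rows.append(pd.Series(imp / total, index=list(features), name=col))
    if not rows:
        raise ValueError("all architecture cells are constant")
    per_cell = pd.DataFrame(rows)
    aggregate = per_cell.mean(axis=0)
    aggregate = aggregate / aggregate.sum()
    return per_cell, aggregate
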