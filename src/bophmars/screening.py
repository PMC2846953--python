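"""Tree-ensemble variable screening: importance ranking, nested predictor
sets with cross-validated R-squared, and large/medium/small set selection.

The screening stage ranks every candidate predictor with a random-forest
importance measure, evaluates the top-k nested sets by k-fold
cross-validated R-squared of a forest restricted to each set, and picks
three working sets: *large* (the full 30-variable set), and *medium* /
*small* at natural cut points of the cv-R2 sequence, operationalized as
the smallest set within a fixed tolerance of the maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSet",
    "rank_variables",
    "build_nested_sets",
    "choose_set_sizes",
    "augment_predictor_set",
]


@dataclass(frozen=True)
class PredictorSet:
    variables: tuple[str, ...]
    cv_r2: float = float("nan")
    size_class: str = "none"

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("predictor set must be non-empty")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("predictor set contains duplicates")
        if self.cv_r2 == self.cv_r2 and self.cv_r2 > 1:
            raise ValueError("cv_r2 cannot exceed 1")


def _forest(n_trees: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=5,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def rank_variables(
    table: pd.DataFrame,
    response: str,
    n_trees: int = 10000,
    seed: int = 0,
    method: str = "permutation",
    exclude: Sequence[str] = (),
    n_permutation_repeats: int = 5,
) -> list[tuple[str, float]]:
    """Rank candidate predictors by random-forest importance, descending.

    ``method`` is ``"permutation"`` (default; robust to the mixed
    continuous/indicator design) or ``"impurity"``.  Importances are
    clipped at zero so every candidate receives a nonnegative score.
    Variables in ``exclude`` (e.g. those trivially related to the target,
    or years-smoked when screening nonsmokers) are dropped up front.
    """
    drop = set(exclude) | {response}
    candidates = [c for c in table.columns if c not in drop]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate predictors to rank")
    X = table[candidates].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    rf = _forest(n_trees, seed).fit(X, y)
    if method == "permutation":
        imp = permutation_importance(
            rf, X, y, n_repeats=n_permutation_repeats, random_state=seed
        ).importances_mean
    elif method == "impurity":
        imp = rf.feature_importances_
    else:
        raise ValueError(f"unknown importance method {method!r}")
    imp = np.clip(imp, 0.0, None)
    order = np.argsort(-imp, kind="stable")
    return [(candidates[i], float(imp[i])) for i in order]


def build_nested_sets(
    ranking: Sequence[tuple[str, float]],
    table: pd.DataFrame,
    response: str,
    max_size: int = 30,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> list[PredictorSet]:
    """Evaluate the nested top-k predictor sets, k = 1..max_size.

    Each set carries the pooled k-fold cross-validated R-squared of a
    random forest restricted to the set.  The fold assignment is seeded
    once and shared across all set sizes so the cv-R2 sequence is
    comparable; it is reported unsmoothed.
    """
    if len(ranking) < max_size:
        raise ValueError(
            f"ranking has {len(ranking)} variables; max_size={max_size}"
        )
    names = [v for v, _ in ranking[:max_size]]
    y = table[response].to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(y))
    out: list[PredictorSet] = []
    for k in range(1, max_size + 1):
        X = table[names[:k]].to_numpy(dtype=float)
        press = 0.0
        for f, (tr, te) in enumerate(splits):
            rf = _forest(n_trees, seed + f).fit(X[tr], y[tr])
            press += float(np.sum((y[te] - rf.predict(X[te])) ** 2))
        out.append(PredictorSet(tuple(names[:k]), cv_r2=1.0 - press / sst))
    return out


def choose_set_sizes(
    sets: Sequence[PredictorSet],
    small_tol: float = 0.02,
    medium_tol: float = 0.005,
) -> tuple[PredictorSet, PredictorSet, PredictorSet]:
    """Choose (large, medium, small) working sets from the cv-R2 sequence.

    Large is the biggest set.  Small is the smallest set whose cv-R2 is
    within ``small_tol`` of the sequence maximum; medium the smallest
    within ``medium_tol`` (never smaller than small).  Ties break toward
    smaller sets.  A flat sequence degenerates to small = medium = 1 with
    a warning.
    """
    if len(sets) < 3:
        raise ValueError("need at least 3 nested sets")
    r2 = np.array([s.cv_r2 for s in sets])
    best = float(r2.max())
    small_k = int(np.argmax(r2 >= best - small_tol))
    medium_k = int(np.argmax(r2 >= best - medium_tol))
    medium_k = max(medium_k, small_k)
    if np.ptp(r2) < 1e-12:
        logger.warning("flat cv_r2 sequence; small = medium = 1")
    large = replace(sets[-1], size_class="large")
    medium = replace(sets[medium_k], size_class="medium")
    small = replace(sets[small_k], size_class="small")
    return large, medium, small


def augment_predictor_set(
    variables: Sequence[str],
    boe_columns: Sequence[str],
    smoking_column: str,
    available: Sequence[str] | None = None,
) -> tuple[str, ...]:
    """Augment a screened set with all exposure biomarkers and the binary
    smoking-status indicator (order-preserving union)."""
    out = list(variables)
    for extra in [*boe_columns, smoking_column]:
        if extra not in out and (available is None or extra in available):
            out.append(extra)
    return tuple(out)
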