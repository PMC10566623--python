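"""Hyperparameter search (grid / random) with k-fold CV on training rows.

Fold assignment is fixed once per call, so every candidate configuration
is scored on identical folds (paired comparison). Configurations that
fail to fit are scored as worst-possible and logged, never fatal unless
every configuration fails.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.metrics import accuracy_score, mean_squared_error, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .data import CLASSIFICATION, REGRESSION
from .model_zoo import GRID, ModelSpec, build_estimator

logger = logging.getLogger(__name__)

MSE = "mse"
ACCURACY = "accuracy"
AUC = "auc"

#: criteria where smaller is better
LOSS_CRITERIA = frozenset({MSE})


class TuningError(RuntimeError):
    pass


def default_criterion(task: str) -> str:
    return MSE if task == REGRESSION else ACCURACY


def is_loss(criterion: str) -> bool:
    return criterion in LOSS_CRITERIA


def worst_score(criterion: str) -> float:
    return math.inf if is_loss(criterion) else -math.inf


def is_better(a: float, b: float, criterion: str, tol: float = 0.0) -> bool:
    """True if score ``a`` improves on ``b`` by strictly more than ``tol``."""
    if is_loss(criterion):
        return a < b - tol
    return a > b + tol


@dataclass
class TuningResult:
    best_params: dict[str, Any]
    best_cv_score: float
    n_configs_evaluated: int
    per_config_scores: list[tuple[dict[str, Any], float]]


def enumerate_grid(param_space: dict[str, list]) -> list[dict[str, Any]]:
    """All combinations, in deterministic (sorted-key, listed-value) order."""
    if not param_space:
        return [{}]
    keys = sorted(param_space)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(param_space[k] for k in keys))
    ]


def draw_random_configs(
    param_space: dict[str, Any], n_draws: int, seed: int
) -> list[dict[str, Any]]:
    """Independent per-parameter draws; duplicates allowed.

    Values may be finite lists or bounded ranges given as tuples
    ``("uniform"|"loguniform", low, high)`` / ``("randint", low, high)``.
    """
    if n_draws < 1:
        raise TuningError("n_draws must be >= 1")
    if not param_space:
        raise TuningError("empty parameter space")
    rng = np.random.default_rng(seed)
    keys = sorted(param_space)
    configs = []
    for _ in range(n_draws):
        cfg = {}
        for k in keys:
            vals = param_space[k]
            if (
                isinstance(vals, tuple)
                and len(vals) == 3
                and vals[0] in ("uniform", "loguniform", "randint")
            ):
                kind, lo, hi = vals
                if kind == "uniform":
                    cfg[k] = float(rng.uniform(lo, hi))
                elif kind == "loguniform":
                    cfg[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    cfg[k] = int(rng.integers(lo, hi))
            else:
                if len(vals) == 0:
                    raise TuningError(f"parameter {k!r} has an empty value list")
                cfg[k] = vals[int(rng.integers(len(vals)))]
        configs.append(cfg)
    return configs


def _score_predictions(y_true, y_pred, y_score, criterion: str) -> float:
    if criterion == MSE:
        return float(mean_squared_error(y_true, y_pred))
    if criterion == ACCURACY:
        return float(accuracy_score(y_true, y_pred))
    if criterion == AUC:
        if y_score is None:
            raise TuningError("AUC criterion needs per-class scores")
        score = np.asarray(y_score)
        labels = np.unique(y_true)
        if labels.size == 2:
            col = score[:, -1] if score.ndim == 2 else score
            return float(roc_auc_score(y_true, col))
        return float(
            roc_auc_score(y_true, score, multi_class="ovr", average="macro")
        )
    raise TuningError(f"unknown criterion {criterion!r}")


def make_folds(y: np.ndarray, cv_folds: int, seed: int, task: str):
    """Seeded fold index pairs, stratified for classification."""
    if task == CLASSIFICATION:
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


def cv_score(
    spec: ModelSpec,
    params: dict[str, Any],
    X: np.ndarray,
    y: np.ndarray,
    folds,
    criterion: str,
    seed: int,
) -> float:
    """Mean criterion across folds; worst-possible on any fit failure."""
    scores = []
    for tr, va in folds:
        try:
            est = build_estimator(spec, params, seed=seed)
            est.fit(X[tr], y[tr])
            y_pred = est.predict(X[va])
            y_score = None
            if criterion == AUC:
                if hasattr(est, "predict_proba"):
                    y_score = est.predict_proba(X[va])
                elif hasattr(est, "decision_function"):
                    y_score = est.decision_function(X[va])
            scores.append(_score_predictions(y[va], y_pred, y_score, criterion))
        except Exception as exc:  # noqa: BLE001 - scored as worst, not fatal
            logger.warning("config %r failed on a fold: %s", params, exc)
            return worst_score(criterion)
    return float(np.mean(scores))


def tune(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    criterion: str | None = None,
    n_random_draws: int | None = None,
) -> TuningResult:
    """Pick the best hyperparameter assignment by k-fold CV.

    Grid strategy enumerates every combination; random strategy draws
    ``n_random_draws`` (default from the spec) independent configs. Ties
    are broken by the first-encountered config in the deterministic
    enumeration order.
    """
    if len(X_train) < cv_folds:
        raise TuningError(
            f"need >= {cv_folds} training rows for {cv_folds}-fold CV"
        )
    criterion = criterion or default_criterion(spec.task)
    if spec.search_strategy == GRID:
        configs = enumerate_grid(spec.param_space)
    else:
        configs = draw_random_configs(
            spec.param_space, n_random_draws or spec.n_random_draws, seed
        )
    folds = make_folds(y_train, cv_folds, seed, spec.task)

    per_config: list[tuple[dict, float]] = []
    best_params, best = None, worst_score(criterion)
    for params in configs:
        score = cv_score(spec, params, X_train, y_train, folds, criterion, seed)
        per_config.append((params, score))
        if best_params is None and np.isfinite(score):
            best_params, best = params, score
        elif is_better(score, best, criterion):
            best_params, best = params, score
    if best_params is None:
        raise TuningError(f"every configuration of {spec.name!r} failed to fit")
    return TuningResult(
        best_params=best_params,
        best_cv_score=best,
        n_configs_evaluated=len(configs),
        per_config_scores=per_config,
    )
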