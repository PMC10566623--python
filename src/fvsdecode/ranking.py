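"""Stage 1: tune, fit and rank every zoo model on one train/test split.

Each registry model is tuned by CV on the training rows, refit with its
best parameters on all training rows, and evaluated on the held-out test
rows; models are ranked by test MSE (ascending) for regression or test
accuracy (descending) for classification. A model that fails outright is
logged and omitted rather than aborting the stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .data import CLASSIFICATION, REGRESSION, Dataset, Split
from .metrics import classification_metrics, regression_metrics
from .model_zoo import FittedModel, fit_model, registry
from .tuning import default_criterion, tune

logger = logging.getLogger(__name__)


@dataclass
class RankRow:
    model: str
    primary_metric: float
    metrics: dict[str, Any]
    params: dict[str, Any]
    n_features: int
    cpu_seconds: float


@dataclass
class RankingTable:
    task: str
    criterion: str
    rows: list[RankRow] = field(default_factory=list)

    @property
    def best(self) -> RankRow:
        return self.rows[0]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {"model": r.model, self.criterion: r.primary_metric}
            for k, v in r.metrics.items():
                if k in (self.criterion, "confusion", "labels", "per_class_recall"):
                    continue
                rec[k] = v
            rec["n_features"] = r.n_features
            rec["cpu_seconds"] = r.cpu_seconds
            rec["params"] = repr(r.params)
            records.append(rec)
        return pd.DataFrame(records)

    def write_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate_fitted(model: FittedModel, X_test: np.ndarray, y_test: np.ndarray) -> dict:
    """Full metric map on held-out data (delegates to the metrics module)."""
    if len(X_test) != len(y_test):
        raise ValueError("X_test and y_test lengths differ")
    y_pred = model.predict(X_test)
    if model.spec.task == REGRESSION:
        return regression_metrics(y_test, y_pred).as_dict()
    scores = model.predict_scores(X_test)
    return classification_metrics(y_test, y_pred, y_score=scores).as_dict()


@dataclass(frozen=True)
class RankConfig:
    cv_folds: int = 5
    seed: int = 0
    criterion: str | None = None
    n_random_draws: int | None = None
    registry_overrides: dict | None = None


def fit_one(
    spec, dataset: Dataset, split: Split, config: RankConfig
) -> tuple[FittedModel, dict, float]:
    """Tune + refit + evaluate a single spec; returns (model, metrics, secs)."""
    criterion = config.criterion or default_criterion(dataset.task)
    seed = derive_seed(config.seed, "rank", spec.name)
    t0 = time.perf_counter()
    X_tr = dataset.X[split.train_idx]
    y_tr = dataset.y[split.train_idx]
    tuned = tune(
        spec,
        X_tr,
        y_tr,
        cv_folds=config.cv_folds,
        seed=seed,
        criterion=criterion,
        n_random_draws=config.n_random_draws,
    )
    model = fit_model(spec, tuned.best_params, X_tr, y_tr, seed=seed)
    metric_map = evaluate_fitted(model, dataset.X[split.test_idx], dataset.y[split.test_idx])
    return model, metric_map, time.perf_counter() - t0


def rank_models(
    dataset: Dataset, split: Split, config: RankConfig | None = None
) -> RankingTable:
    """Rank the full zoo for the dataset's task on one split."""
    config = config or RankConfig()
    criterion = config.criterion or default_criterion(dataset.task)
    primary_key = "mse" if dataset.task == REGRESSION else "accuracy"
    rows: list[RankRow] = []
    for spec in registry(dataset.task, config.registry_overrides):
        try:
            model, metric_map, secs = fit_one(spec, dataset, split, config)
        except Exception as exc:  # noqa: BLE001 - one family must not kill the stage
            logger.error("model %r failed and is omitted: %s", spec.name, exc)
            continue
        rows.append(
            RankRow(
                model=spec.name,
                primary_metric=float(metric_map[primary_key]),
                metrics=metric_map,
                params=model.params,
                n_features=dataset.m,
                cpu_seconds=secs,
            )
        )
    if not rows:
        raise RuntimeError("every model failed; empty ranking table")
    reverse = dataset.task == CLASSIFICATION  # accuracy: descending
    rows.sort(key=lambda r: r.primary_metric, reverse=reverse)
    return RankingTable(task=dataset.task, criterion=primary_key, rows=rows)
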