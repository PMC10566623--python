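"""Stage 2: greedy forward variable selection.

At each iteration the samples are (re)split 70/30, every not-yet-selected
feature is scored by tuning the chosen model with k-fold CV on the
training rows restricted to the current set plus that candidate, refit
and evaluated on the test rows; the best-scoring candidate is appended if
it improves on the previous step by more than the tolerance, otherwise
selection stops. Candidate evaluations are independent and can run on
worker processes; per-candidate seeds are derived from
(master_seed, iteration, feature index), never from worker identity, so
any worker count produces the identical trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._seeds import derive_seed
from .data import CLASSIFICATION, Dataset, Split, SplitConfig, make_split
from .model_zoo import ModelSpec, fit_model, get_spec
from .tuning import (
    AUC,
    _score_predictions,
    default_criterion,
    is_better,
    tune,
    worst_score,
)

logger = logging.getLogger(__name__)

NO_IMPROVEMENT = "no_improvement"
CAP_REACHED = "cap_reached"


@dataclass(frozen=True)
class FvsConfig:
    model_name: str
    n_selected_features: int | None = None  # None = all features (m)
    improvement_tol: float = 0.0
    resplit_each_iteration: bool = True
    master_seed: int = 0
    n_workers: int = 1
    cv_folds: int = 5
    train_fraction: float = 0.7
    criterion: str | None = None  # default: mse / accuracy by task
    n_random_draws: int | None = None
    tune_every: int = 1  # retune every k-th iteration; params reused between
    registry_overrides: dict | None = None

    def __post_init__(self) -> None:
        if self.n_selected_features is not None and self.n_selected_features < 1:
            raise ValueError("n_selected_features must be >= 1 (nothing to select)")
        if self.improvement_tol < 0:
            raise ValueError("improvement_tol must be >= 0")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.tune_every < 1:
            raise ValueError("tune_every must be >= 1")


@dataclass
class FvsStep:
    iteration: int
    feature: str
    score: float
    params: dict[str, Any]
    candidate_scores: dict[str, float] | None = None


@dataclass
class SelectionTrace:
    steps: list[FvsStep] = field(default_factory=list)
    stop_reason: str = CAP_REACHED
    criterion: str = "mse"
    model_name: str = ""

    @property
    def selected_features(self) -> list[str]:
        return [s.feature for s in self.steps]

    @property
    def final_score(self) -> float | None:
        return self.steps[-1].score if self.steps else None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": s.iteration,
                    "feature": s.feature,
                    self.criterion: s.score,
                    "params": repr(s.params),
                }
                for s in self.steps
            ]
        )

    def write_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def partition_candidates(
    candidates: list, n_workers: int, seed: int
) -> list[list]:
    """Randomly assign candidates to ``n_workers`` near-equal queues.

    Subsets are disjoint, cover all candidates, and their sizes differ by
    at most one; the assignment is reproducible given the seed.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if not candidates:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    n_queues = min(n_workers, len(candidates))
    queues: list[list] = [[] for _ in range(n_queues)]
    for pos, idx in enumerate(order):
        queues[pos % n_queues].append(candidates[idx])
    return queues


def score_candidate(
    dataset: Dataset,
    selected: list[str],
    candidate: str,
    spec: ModelSpec,
    split: Split,
    seed: int,
    criterion: str | None = None,
    cv_folds: int = 5,
    n_random_draws: int | None = None,
    params: dict[str, Any] | None = None,
) -> tuple[float, dict[str, Any]]:
    """Tune -> refit -> score the model on ``selected + candidate`` columns.

    Pure function of its arguments: identical inputs give identical
    scores regardless of scheduling. When ``params`` is given, tuning is
    skipped and the assignment is reused. Fit failures yield the
    worst-possible score.
    """
    if candidate in selected:
        raise ValueError(f"candidate {candidate!r} already selected")
    criterion = criterion or default_criterion(dataset.task)
    sub = dataset.select_features(list(selected) + [candidate])
    X_tr, y_tr = sub.X[split.train_idx], sub.y[split.train_idx]
    X_te, y_te = sub.X[split.test_idx], sub.y[split.test_idx]
    try:
        if params is None:
            tuned = tune(
                spec,
                X_tr,
                y_tr,
                cv_folds=cv_folds,
                seed=seed,
                criterion=criterion,
                n_random_draws=n_random_draws,
            )
            params = tuned.best_params
        model = fit_model(spec, params, X_tr, y_tr, seed=seed)
        y_pred = model.predict(X_te)
        y_score = model.predict_scores(X_te) if criterion == AUC else None
        return _score_predictions(y_te, y_pred, y_score, criterion), params
    except Exception as exc:  # noqa: BLE001 - candidate scored worst, not fatal
        logger.warning("candidate %r failed: %s", candidate, exc)
        return worst_score(criterion), dict(params or {})


def _score_batch(dataset, selected, batch, spec, split, seeds, criterion,
                 cv_folds, n_random_draws, params):
    return [
        score_candidate(
            dataset, selected, cand, spec, split, seeds[cand],
            criterion=criterion, cv_folds=cv_folds,
            n_random_draws=n_random_draws, params=params,
        )
        for cand in batch
    ]


def forward_select(dataset: Dataset, config: FvsConfig) -> SelectionTrace:
    """Run greedy forward selection and return the trace.

    The empty-set baseline is worst-possible, so the first feature is
    always accepted; afterwards a candidate is appended only if it
    improves the step score by strictly more than ``improvement_tol``.
    Ties between candidates are broken by the lowest feature index.
    """
    spec = get_spec(config.model_name, dataset.task, config.registry_overrides)
    criterion = config.criterion or default_criterion(dataset.task)
    cap = config.n_selected_features or dataset.m
    cap = min(cap, dataset.m)
    if dataset.n < 10:
        raise ValueError("forward selection needs at least 10 samples")

    feat_index = {f: j for j, f in enumerate(dataset.feature_names)}
    selected: list[str] = []
    trace = SelectionTrace(criterion=criterion, model_name=config.model_name)
    best_so_far = worst_score(criterion)
    split: Split | None = None
    reuse_params: dict[str, Any] | None = None

    pool = (
        Parallel(n_jobs=config.n_workers, batch_size=1)
        if config.n_workers > 1
        else None
    )

    for t in range(cap):
        if split is None or config.resplit_each_iteration:
            split_seed = derive_seed(config.master_seed, "split", t)
            split = make_split(
                dataset,
                SplitConfig(
                    train_fraction=config.train_fraction,
                    cv_folds=config.cv_folds,
                    seed=split_seed,
                    stratified=dataset.task == CLASSIFICATION,
                ),
            )
        candidates = [f for f in dataset.feature_names if f not in selected]
        seeds = {
            f: derive_seed(config.master_seed, t, feat_index[f]) for f in candidates
        }
        tune_now = t % config.tune_every == 0
        params_arg = None if tune_now else reuse_params

        if pool is None:
            results = _score_batch(
                dataset, selected, candidates, spec, split, seeds,
                criterion, config.cv_folds, config.n_random_draws, params_arg,
            )
            by_feature = dict(zip(candidates, results))
        else:
            batches = partition_candidates(
                candidates,
                config.n_workers,
                seed=derive_seed(config.master_seed, "partition", t),
            )
            batch_results = pool(
                delayed(_score_batch)(
                    dataset, selected, batch, spec, split, seeds,
                    criterion, config.cv_folds, config.n_random_draws, params_arg,
                )
                for batch in batches
            )
            by_feature = {
                cand: res
                for batch, results in zip(batches, batch_results)
                for cand, res in zip(batch, results)
            }

        # best candidate, ties broken by lowest feature index
        best_feat, best_score, best_params = None, worst_score(criterion), {}
        for f in sorted(candidates, key=feat_index.get):
            score, params = by_feature[f]
            if best_feat is None or is_better(score, best_score, criterion):
                best_feat, best_score, best_params = f, score, params

        if not is_better(best_score, best_so_far, criterion, config.improvement_tol):
            trace.stop_reason = NO_IMPROVEMENT
            logger.info(
                "stopping at iteration %d: best candidate %r (%s=%.6g) does not "
                "improve on %.6g",
                t, best_feat, criterion, best_score, best_so_far,
            )
            break
        selected.append(best_feat)
        reuse_params = best_params
        best_so_far = best_score
        trace.steps.append(
            FvsStep(
                iteration=t,
                feature=best_feat,
                score=float(best_score),
                params=dict(best_params),
                candidate_scores={f: float(s) for f, (s, _) in by_feature.items()},
            )
        )
        logger.info(
            "iteration %d: selected %r (%s=%.6g)", t, best_feat, criterion, best_score
        )
    else:
        trace.stop_reason = CAP_REACHED
    return trace
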