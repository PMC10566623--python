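"""Registry of estimator families with hyperparameter spaces.

The regression zoo holds 11 families and the classification zoo 7; each
entry carries a declarative parameter space and a search strategy (grid
for small spaces, random for tree ensembles and other large spaces). The
registry can be extended or overridden from a YAML/JSON config.

Concrete grid values are conventional defaults (log-spaced shrinkage
grids, small depth/tree-count menus); they are all defined here in one
place so users can override any of them.
"""

from __future__ import annotations

import inspect
import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as gp_kernels
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import (
    ElasticNet,
    Lars,
    Lasso,
    LassoLars,
    LogisticRegression,
    MultiTaskLasso,
    Ridge,
    SGDRegressor,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data import CLASSIFICATION, REGRESSION, TASKS

GRID = "grid"
RANDOM = "random"

#: Upper bound on the size of any grid-strategy space (tuning must
#: terminate at desk scale).
MAX_GRID_SIZE = 10_000

_SHRINKAGE = [float(a) for a in np.logspace(-4, 4, 9)]

_TREE_DEPTHS = [2, 4, 8, 16, None]
_TREE_COUNTS = [50, 100, 250, 500]


class ZooError(ValueError):
    """Raised for unknown tasks, model names or malformed specs."""


@dataclass(frozen=True)
class ModelSpec:
    """One zoo entry: estimator family plus its tuning space."""

    name: str
    task: str
    estimator_family: str
    param_space: dict[str, Any]
    search_strategy: str
    n_random_draws: int = 50

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ZooError(f"unknown task {self.task!r}")
        if self.search_strategy not in (GRID, RANDOM):
            raise ZooError(f"unknown search strategy {self.search_strategy!r}")
        if self.search_strategy == GRID:
            size = 1
            for key, vals in self.param_space.items():
                if not isinstance(vals, (list, tuple)) or isinstance(vals[0], str) and vals[0] in _DISTS:
                    raise ZooError(
                        f"grid spec {self.name!r}: parameter {key!r} must be a finite list"
                    )
                size *= len(vals)
            if size > MAX_GRID_SIZE:
                raise ZooError(
                    f"grid for {self.name!r} has {size} points (> {MAX_GRID_SIZE})"
                )
        if self.n_random_draws < 1:
            raise ZooError("n_random_draws must be >= 1")

    def grid_size(self) -> int | None:
        if self.search_strategy != GRID:
            return None
        return math.prod(len(v) for v in self.param_space.values())


_DISTS = ("uniform", "loguniform", "randint")


def _mtl_space() -> dict:
    return {"alpha": list(_SHRINKAGE)}


def _tree_space(task: str) -> dict:
    criterion = (
        ["squared_error", "absolute_error"]
        if task == REGRESSION
        else ["gini", "entropy"]
    )
    return {
        "max_depth": list(_TREE_DEPTHS),
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 5],
        "criterion": criterion,
        "splitter": ["best", "random"],
        "max_features": [None, "sqrt", "log2"],
    }


def _forest_space(task: str) -> dict:
    space = _tree_space(task)
    # forests have no splitter choice; key kept (single value) so the
    # forest space remains a superset of the tree space
    space["splitter"] = ["best"]
    space["n_estimators"] = list(_TREE_COUNTS)
    return space


def _boosting_space() -> dict:
    return {
        "loss": ["log_loss"],
        "criterion": ["friedman_mse", "squared_error"],
        "n_estimators": [50, 100, 250],
        "learning_rate": [0.01, 0.1, 0.3],
        "max_depth": [2, 3, 5],
    }


def _default_specs(task: str) -> list[ModelSpec]:
    if task == REGRESSION:
        return [
            ModelSpec("ridge", task, "ridge", {"alpha": list(_SHRINKAGE)}, GRID),
            ModelSpec("lasso", task, "lasso", {"alpha": list(_SHRINKAGE)}, GRID),
            ModelSpec(
                "kernel_ridge",
                task,
                "kernel_ridge",
                {
                    "kernel": ["linear", "laplacian", "rbf", "sigmoid"],
                    "alpha": [1e-3, 1e-1, 1.0, 10.0],
                    "gamma": [1e-3, 1e-2, 1e-1, 1.0],
                },
                GRID,
            ),
            ModelSpec("multitask_lasso", task, "multitask_lasso", _mtl_space(), GRID),
            ModelSpec(
                "lar",
                task,
                "lar",
                {"n_nonzero_coefs": [1, 2, 4, 8, 16, 32, 64, 128, 500]},
                GRID,
            ),
            ModelSpec("lassolar", task, "lassolar", {"alpha": list(_SHRINKAGE)}, GRID),
            ModelSpec(
                "elastic_net",
                task,
                "elastic_net",
                {
                    "alpha": list(_SHRINKAGE),
                    "l1_ratio": [0.1, 0.3, 0.5, 0.7, 0.9],
                },
                GRID,
            ),
            ModelSpec(
                "sgd_regressor",
                task,
                "sgd_regressor",
                {
                    "loss": ["squared_error", "huber", "epsilon_insensitive"],
                    "penalty": ["l2", "l1", "elasticnet"],
                    "learning_rate": ["constant", "optimal", "invscaling", "adaptive"],
                    "alpha": [1e-5, 1e-4, 1e-3, 1e-2],
                },
                RANDOM,
            ),
            ModelSpec("decision_tree", task, "decision_tree", _tree_space(task), RANDOM),
            ModelSpec("random_forest", task, "random_forest", _forest_space(task), RANDOM),
            ModelSpec(
                "gaussian_process",
                task,
                "gaussian_process",
                {
                    "kernel": ["rbf", "matern", "rational_quadratic", "dot_product"],
                    "length_scale": [0.1, 1.0, 10.0],
                    "noise_level": [1e-6, 1e-3, 1e-1],
                },
                RANDOM,
            ),
        ]
    if task == CLASSIFICATION:
        gb = _boosting_space()
        xgb = dict(gb)
        xgb["n_parallel_trees"] = [1]
        return [
            ModelSpec("decision_tree", task, "decision_tree", _tree_space(task), RANDOM),
            ModelSpec("random_forest", task, "random_forest", _forest_space(task), RANDOM),
            ModelSpec("gradient_boosting", task, "gradient_boosting", gb, RANDOM),
            ModelSpec(
                "extreme_gradient_boosting",
                task,
                "extreme_gradient_boosting",
                xgb,
                RANDOM,
            ),
            ModelSpec(
                "extremely_randomized_trees",
                task,
                "extremely_randomized_trees",
                {
                    "n_estimators": list(_TREE_COUNTS),
                    "max_depth": list(_TREE_DEPTHS),
                    "criterion": ["gini", "entropy"],
                    "max_features": [None, "sqrt", "log2"],
                    "bootstrap": [False],
                },
                RANDOM,
            ),
            ModelSpec(
                "logistic_l1",
                task,
                "logistic_l1",
                {"l1_ratio": [0.0, 0.25, 0.5, 0.75, 1.0], "C": [0.01, 0.1, 1.0, 10.0]},
                GRID,
            ),
            ModelSpec(
                "naive_bayes",
                task,
                "naive_bayes",
                {"var_smoothing": [1e-12, 1e-9, 1e-6, 1e-3, 1e-1]},
                GRID,
            ),
        ]
    raise ZooError(f"unknown task {task!r}")


def registry(task: str, overrides: dict | None = None) -> list[ModelSpec]:
    """Return the zoo for ``task``, optionally patched/extended.

    ``overrides`` maps model name to a dict with any of ``param_space``,
    ``search_strategy``, ``n_random_draws`` and (for new entries)
    ``estimator_family``.
    """
    specs = {s.name: s for s in _default_specs(task)}
    for name, patch in (overrides or {}).items():
        patch = dict(patch)
        family = patch.pop("estimator_family", None)
        if name in specs:
            specs[name] = replace(specs[name], **patch)
        else:
            if family is None:
                raise ZooError(
                    f"new registry entry {name!r} needs an estimator_family"
                )
            specs[name] = ModelSpec(
                name=name,
                task=task,
                estimator_family=family,
                param_space=patch.get("param_space", {}),
                search_strategy=patch.get("search_strategy", RANDOM),
                n_random_draws=patch.get("n_random_draws", 50),
            )
    return list(specs.values())


def get_spec(name: str, task: str, overrides: dict | None = None) -> ModelSpec:
    for spec in registry(task, overrides):
        if spec.name == name:
            return spec
    raise ZooError(f"unknown model {name!r} for task {task!r}")


def default_param_space(name: str, task: str) -> dict[str, Any]:
    return dict(get_spec(name, task).param_space)


class _MultiTaskLassoSingle(MultiTaskLasso):
    """MultiTaskLasso adapted to a single target (one-column multi-output)."""

    def fit(self, X, y):  # noqa: D102
        return super().fit(X, np.asarray(y).reshape(-1, 1))

    def predict(self, X):  # noqa: D102
        return super().predict(X).ravel()


def _gp_kernel(params: dict) -> gp_kernels.Kernel:
    name = params.get("kernel", "rbf")
    scale = params.get("length_scale", 1.0)
    noise = params.get("noise_level", 1e-6)
    base = {
        "rbf": lambda: gp_kernels.RBF(length_scale=scale),
        "matern": lambda: gp_kernels.Matern(length_scale=scale),
        "rational_quadratic": lambda: gp_kernels.RationalQuadratic(length_scale=scale),
        "dot_product": lambda: gp_kernels.DotProduct(sigma_0=scale),
    }
    if name not in base:
        raise ZooError(f"unknown gaussian_process kernel {name!r}")
    return gp_kernels.ConstantKernel(1.0) * base[name]() + gp_kernels.WhiteKernel(
        noise_level=noise
    )


_FAMILIES: dict[tuple[str, str], type] = {
    (REGRESSION, "ridge"): Ridge,
    (REGRESSION, "lasso"): Lasso,
    (REGRESSION, "kernel_ridge"): KernelRidge,
    (REGRESSION, "multitask_lasso"): _MultiTaskLassoSingle,
    (REGRESSION, "lar"): Lars,
    (REGRESSION, "lassolar"): LassoLars,
    (REGRESSION, "elastic_net"): ElasticNet,
    (REGRESSION, "sgd_regressor"): SGDRegressor,
    (REGRESSION, "decision_tree"): DecisionTreeRegressor,
    (REGRESSION, "random_forest"): RandomForestRegressor,
    (REGRESSION, "gaussian_process"): GaussianProcessRegressor,
    (CLASSIFICATION, "decision_tree"): DecisionTreeClassifier,
    (CLASSIFICATION, "random_forest"): RandomForestClassifier,
    (CLASSIFICATION, "gradient_boosting"): GradientBoostingClassifier,
    # xgboost is not available offline; the histogram-based gradient
    # booster is the drop-in equivalent implementation.
    (CLASSIFICATION, "extreme_gradient_boosting"): HistGradientBoostingClassifier,
    (CLASSIFICATION, "extremely_randomized_trees"): ExtraTreesClassifier,
    (CLASSIFICATION, "logistic_l1"): LogisticRegression,
    (CLASSIFICATION, "naive_bayes"): GaussianNB,
}

# fixed constructor arguments, applied before the tuned parameters
_FAMILY_FIXED: dict[str, dict] = {
    "lasso": {"max_iter": 10_000},
    "elastic_net": {"max_iter": 10_000},
    "multitask_lasso": {"max_iter": 10_000},
    "sgd_regressor": {"max_iter": 2_000, "eta0": 0.01, "tol": 1e-4},
    "logistic_l1": {"solver": "saga", "max_iter": 5_000},
    "gaussian_process": {"normalize_y": True},
    "extreme_gradient_boosting": {"early_stopping": False},
}

# declarative key -> constructor keyword, per family
_FAMILY_RENAMES: dict[str, dict[str, str]] = {
    "extreme_gradient_boosting": {"n_estimators": "max_iter"},
}


@dataclass
class FittedModel:
    """A tuned, fitted estimator with its provenance."""

    spec: ModelSpec
    params: dict[str, Any]
    estimator: Any
    classes_: np.ndarray | None = field(default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def predict_scores(self, X: np.ndarray) -> np.ndarray | None:
        """Per-class scores (probabilities if available), classification only."""
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)
        if hasattr(self.estimator, "decision_function"):
            return self.estimator.decision_function(X)
        return None


def build_estimator(spec: ModelSpec, params: dict[str, Any], seed: int = 0):
    """Instantiate the estimator for ``spec`` with a tuned assignment.

    Declarative parameters not accepted by the underlying constructor
    (e.g. ``splitter`` for forests, ``n_parallel_trees`` for the
    histogram booster) are dropped; ``random_state`` is set when the
    estimator supports it.
    """
    key = (spec.task, spec.estimator_family)
    if key not in _FAMILIES:
        raise ZooError(
            f"no estimator for family {spec.estimator_family!r} / task {spec.task!r}"
        )
    cls = _FAMILIES[key]
    kwargs = dict(_FAMILY_FIXED.get(spec.estimator_family, {}))
    renames = _FAMILY_RENAMES.get(spec.estimator_family, {})
    if spec.estimator_family == "gaussian_process":
        kwargs["kernel"] = _gp_kernel(params)
        params = {
            k: v for k, v in params.items()
            if k not in ("kernel", "length_scale", "noise_level")
        }
    if spec.estimator_family == "logistic_l1":
        # pure-L1/L2 endpoints of the mixing parameter have much faster
        # dedicated solvers than saga; the optimum is the same
        ratio = params.get("l1_ratio")
        if ratio == 1.0:
            kwargs["solver"] = "liblinear"
        elif ratio == 0.0:
            kwargs["solver"] = "lbfgs"
    accepted = set(inspect.signature(cls.__init__).parameters)
    for k, v in params.items():
        k = renames.get(k, k)
        if k in accepted:
            kwargs[k] = v
    if "random_state" in accepted:
        kwargs["random_state"] = seed
    return cls(**kwargs)


def fit_model(
    spec: ModelSpec, params: dict[str, Any], X: np.ndarray, y: np.ndarray, seed: int = 0
) -> FittedModel:
    est = build_estimator(spec, params, seed=seed)
    est.fit(X, y)
    classes = getattr(est, "classes_", None)
    return FittedModel(spec=spec, params=dict(params), estimator=est, classes_=classes)
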