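"""All-relevant feature selection by shadow-feature permutation.

Each iteration appends one permuted (shadow) copy of every undecided
feature, fits a random forest on originals plus shadows, and counts a
"hit" for every original whose importance exceeds the maximum shadow
importance. Hit counts are compared to a Binomial(iterations, 1/2) null
with a two-sided test at level alpha, Bonferroni-corrected across the
features still undecided; significantly-high features are accepted,
significantly-low ones rejected, and survivors at the iteration cap stay
tentative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance

from ._seeds import derive_seed
from .data import CLASSIFICATION, Dataset

logger = logging.getLogger(__name__)

ACCEPTED = "accepted"
REJECTED = "rejected"
TENTATIVE = "tentative"

#: iterations before the first binomial test (counts are meaningless earlier)
_MIN_ITER_FOR_TEST = 5


@dataclass(frozen=True)
class BorutaConfig:
    max_iter: int = 100
    alpha: float = 0.05
    n_trees: int = 100
    seed: int = 0
    max_features_considered: int | None = None  # None = all m features
    importance: str = "impurity"  # or "permutation"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")


@dataclass
class BorutaResult:
    decisions: dict[str, str]
    hits: dict[str, int]
    trials: dict[str, int]
    importance_history: dict[str, list[float]]
    shadow_max_history: list[float]
    z_history: dict[str, list[float]]
    n_iterations: int

    @property
    def accepted(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == ACCEPTED]

    @property
    def rejected(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == TENTATIVE]

    def mean_z(self, feature: str) -> float:
        zs = self.z_history.get(feature, [])
        return float(np.mean(zs)) if zs else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": f,
                    "decision": d,
                    "mean_z": self.mean_z(f),
                    "hits": self.hits[f],
                    "iterations": self.trials[f],
                }
                for f, d in self.decisions.items()
            ]
        )

    def write_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _importances(forest, X, y, kind: str, seed: int) -> np.ndarray:
    if kind == "impurity":
        return forest.feature_importances_
    res = permutation_importance(forest, X, y, n_repeats=5, random_state=seed)
    return res.importances_mean


def boruta_select(dataset: Dataset, config: BorutaConfig | None = None) -> BorutaResult:
    """Run the shadow-feature selector on every dataset feature.

    Classification uses a random-forest classifier as in the canonical
    formulation; regression targets are supported through the
    random-forest regressor.
    """
    config = config or BorutaConfig()
    names = dataset.feature_names
    if config.max_features_considered is not None:
        names = names[: config.max_features_considered]
    idx = {f: j for j, f in enumerate(dataset.feature_names)}

    rng = np.random.default_rng(derive_seed(config.seed, "boruta"))
    decisions = {f: TENTATIVE for f in names}
    hits = {f: 0 for f in names}
    trials = {f: 0 for f in names}
    imp_hist: dict[str, list[float]] = {f: [] for f in names}
    z_hist: dict[str, list[float]] = {f: [] for f in names}
    shadow_max_hist: list[float] = []

    forest_cls = (
        RandomForestClassifier if dataset.task == CLASSIFICATION else RandomForestRegressor
    )

    n_iter = 0
    for it in range(1, config.max_iter + 1):
        undecided = [f for f in names if decisions[f] == TENTATIVE]
        if not undecided:
            break
        n_iter = it
        cols = [idx[f] for f in undecided]
        X_orig = dataset.X[:, cols]
        shadows = np.empty_like(X_orig)
        for j in range(X_orig.shape[1]):
            shadows[:, j] = rng.permutation(X_orig[:, j])
        X_all = np.hstack([X_orig, shadows])

        forest = forest_cls(
            n_estimators=config.n_trees,
            random_state=derive_seed(config.seed, "forest", it),
            n_jobs=1,
        )
        forest.fit(X_all, dataset.y)
        imp = _importances(
            forest, X_all, dataset.y, config.importance,
            derive_seed(config.seed, "perm", it),
        )
        k = len(undecided)
        imp_orig, imp_shadow = imp[:k], imp[k:]
        shadow_max = float(imp_shadow.max())
        shadow_mean = float(imp_shadow.mean())
        shadow_sd = float(imp_shadow.std(ddof=1)) if k > 1 else 0.0
        shadow_max_hist.append(shadow_max)

        for f, v in zip(undecided, imp_orig):
            trials[f] += 1
            if v > shadow_max:
                hits[f] += 1
            imp_hist[f].append(float(v))
            if shadow_sd > 0:
                z_hist[f].append((float(v) - shadow_mean) / shadow_sd)

        if it >= _MIN_ITER_FOR_TEST:
            level = config.alpha / len(undecided)  # Bonferroni
            for f in undecided:
                p_high = stats.binom.sf(hits[f] - 1, trials[f], 0.5)
                p_low = stats.binom.cdf(hits[f], trials[f], 0.5)
                if p_high < level / 2:
                    decisions[f] = ACCEPTED
                    logger.info("iteration %d: accepted %r", it, f)
                elif p_low < level / 2:
                    decisions[f] = REJECTED
                    logger.info("iteration %d: rejected %r", it, f)

    return BorutaResult(
        decisions=decisions,
        hits=hits,
        trials=trials,
        importance_history=imp_hist,
        shadow_max_history=shadow_max_hist,
        z_history=z_hist,
        n_iterations=n_iter,
    )
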