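"""Synthetic ROI-table generator.

Produces datasets with the statistical structure of regional-volume
tables: equicorrelated continuous features, a small planted informative
subset driving a latent score, an ordinal or binary/multiclass target
derived from that score, and a TIV-like global covariate correlated with
many features. Ground truth (informative names and generating
coefficients) is returned alongside so recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CLASSIFICATION, REGRESSION, Dataset


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n: int = 300
    m: int = 100
    k: int = 5
    effect: float = 2.0
    rho: float = 0.3
    covariate_strength: float = 1.0
    task: str = REGRESSION
    n_classes: int = 2
    n_ordinal_levels: int = 0  # 0 keeps the regression target continuous
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.m:
            raise SimulationError(f"k={self.k} informative features but only m={self.m}")
        if not 0.0 <= self.rho < 1.0:
            raise SimulationError("rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.task == CLASSIFICATION and self.n_classes < 2:
            raise SimulationError("need at least 2 classes")


@dataclass
class GroundTruth:
    informative_features: list[str]
    coefficients: dict[str, float]
    latent: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "informative_features": self.informative_features,
            "coefficients": self.coefficients,
        }


def _equicorrelated(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    # X_j = sqrt(rho)*g + sqrt(1-rho)*e_j gives pairwise correlation rho
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, m))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique


def _ordinalize(latent: np.ndarray, levels: int) -> np.ndarray:
    """Equal-frequency discretization into codes 0..levels-1."""
    qs = np.quantile(latent, np.linspace(0, 1, levels + 1)[1:-1])
    return np.searchsorted(qs, latent, side="right").astype(float)


def simulate(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset plus its ground truth, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    X = _equicorrelated(rng, config.n, config.m, config.rho)
    names = [f"roi_{j:03d}" for j in range(config.m)]

    informative = np.sort(rng.choice(config.m, size=config.k, replace=False))
    # alternating signs keep the latent nearly orthogonal to the shared
    # equicorrelation factor; otherwise averages of non-informative
    # features proxy the signal and the planted set is unidentifiable
    signs = np.where(np.arange(config.k) % 2 == 0, 1.0, -1.0)
    beta = signs * config.effect
    latent = X[:, informative] @ beta + config.noise_sd * rng.standard_normal(config.n)

    if config.task == REGRESSION:
        if config.n_ordinal_levels >= 2:
            y = _ordinalize(latent, config.n_ordinal_levels)
        else:
            y = latent.copy()
    elif config.task == CLASSIFICATION:
        if config.n_classes == 2:
            y = (latent > np.median(latent)).astype(int)
        else:
            y = _ordinalize(latent, config.n_classes).astype(int)
    else:
        raise SimulationError(f"unknown task {config.task!r}")

    covariates = None
    cov_names: list[str] = []
    if config.covariate_strength != 0.0:
        w = rng.uniform(0.5, 1.5, size=config.m) / config.m
        tiv = config.covariate_strength * (X @ w) + 0.1 * rng.standard_normal(config.n)
        covariates = tiv[:, None]
        cov_names = ["TIV"]

    dataset = Dataset(
        X=X,
        y=y,
        feature_names=names,
        task=config.task,
        covariates=covariates,
        covariate_names=cov_names,
    )
    truth = GroundTruth(
        informative_features=[names[j] for j in informative],
        coefficients={names[j]: float(b) for j, b in zip(informative, beta)},
        latent=latent,
    )
    return dataset, truth
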