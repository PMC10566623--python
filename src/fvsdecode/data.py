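"""Tabular data model, table I/O, splitting, and covariate control.

A :class:`Dataset` is a plain samples x features matrix with a target
vector and (optionally) nuisance covariates such as total intracranial
volume. Covariates are removed by per-feature OLS residualization whose
coefficients are estimated on training rows only, so the held-out split
never leaks into the adjustment.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

REGRESSION = "regression"
CLASSIFICATION = "classification"
TASKS = (REGRESSION, CLASSIFICATION)


class DataError(ValueError):
    """Raised for malformed input tables or invalid dataset states."""


@dataclass
class Dataset:
    """Feature matrix, target and optional covariates for one problem.

    Parameters
    ----------
    X : ndarray of shape (n, m)
        Feature matrix, no missing values.
    y : ndarray of shape (n,)
        Target. Real-valued for regression; class labels (any hashable
        scalar type) for classification.
    feature_names : list of str
        Unique names, one per column of ``X``.
    task : {"regression", "classification"}
    covariates : ndarray of shape (n, c), optional
        Nuisance covariates (e.g. TIV), removable via
        :func:`residualize_covariates`.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    task: str
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    target_name: str = "target"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.task not in TASKS:
            raise DataError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.X.ndim != 2:
            raise DataError("X must be 2-dimensional")
        n, m = self.X.shape
        if len(self.feature_names) != m:
            raise DataError(
                f"{len(self.feature_names)} feature names for {m} columns"
            )
        if len(set(self.feature_names)) != m:
            raise DataError("feature names must be unique")
        if len(self.y) != n:
            raise DataError(f"y has length {len(self.y)}, X has {n} rows")
        if np.isnan(self.X).any():
            raise DataError("X contains missing values")
        if self.task == CLASSIFICATION and len(np.unique(self.y)) < 2:
            raise DataError("classification target needs >= 2 distinct labels")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise DataError("covariate rows do not match X rows")
            if not self.covariate_names:
                self.covariate_names = [
                    f"cov{j}" for j in range(self.covariates.shape[1])
                ]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def select_features(self, names: list[str]) -> "Dataset":
        """Return a copy restricted to ``names`` (kept in dataset order)."""
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise DataError(f"unknown feature(s): {missing}")
        cols = sorted(index[f] for f in names)
        return replace(
            self,
            X=self.X[:, cols],
            feature_names=[self.feature_names[j] for j in cols],
        )

    def summary(self) -> dict:
        out = {"n": self.n, "m": self.m, "task": self.task}
        if self.task == CLASSIFICATION:
            labels, counts = np.unique(self.y, return_counts=True)
            out["class_counts"] = {str(k): int(v) for k, v in zip(labels, counts)}
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.7
    cv_folds: int = 5
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise DataError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise DataError("cv_folds must be >= 2")


@dataclass(frozen=True)
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        both = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if not np.array_equal(both, np.arange(len(both))):
            raise DataError("train/test indices must be disjoint and exhaustive")


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_table(
    path: str,
    target_column: str,
    covariate_columns: list[str] | None = None,
    task: str = REGRESSION,
    drop_na: bool = False,
) -> Dataset:
    """Load a delimited text table (CSV/TSV, header row required).

    Features are all numeric columns other than the target and covariates,
    in file order. Entirely non-numeric columns (typical ID columns) are
    ignored with a warning. Rows with missing feature/target/covariate
    values are fatal unless ``drop_na`` is set, in which case they are
    dropped; values are never imputed.
    """
    covariate_columns = list(covariate_columns or [])
    delim = _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=delim))
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise DataError(f"duplicate column name(s) in header: {sorted(dupes)}")

    df = pd.read_csv(path, sep=delim)
    if target_column not in df.columns:
        raise DataError(f"target column {target_column!r} not found in {path}")
    for c in covariate_columns:
        if c not in df.columns:
            raise DataError(f"covariate column {c!r} not found in {path}")

    # Classify remaining columns: numeric features vs ignorable ID columns.
    feature_cols: list[str] = []
    for c in df.columns:
        if c == target_column or c in covariate_columns:
            continue
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.all() and len(df) > 0:
            logger.warning("ignoring non-numeric column %r", c)
            continue
        if bad.any():
            row = int(bad.idxmax())
            raise DataError(
                f"non-numeric value {df[c][row]!r} in feature column {c!r}, row {row}"
            )
        df[c] = coerced
        feature_cols.append(c)
    if not feature_cols:
        raise DataError("no numeric feature columns found")

    if task == REGRESSION:
        y_ser = pd.to_numeric(df[target_column], errors="coerce")
        bad = y_ser.isna() & df[target_column].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DataError(
                f"non-numeric target value in column {target_column!r}, row {row}"
            )
    else:
        y_ser = df[target_column]

    cov_df = df[covariate_columns].apply(pd.to_numeric, errors="coerce")
    na_mask = df[feature_cols].isna().any(axis=1) | y_ser.isna()
    if covariate_columns:
        na_mask |= cov_df.isna().any(axis=1)
    if na_mask.any():
        if not drop_na:
            row = int(na_mask.idxmax())
            bad_cols = [
                c
                for c in feature_cols + [target_column] + covariate_columns
                if pd.isna(df.loc[row, c])
            ]
            raise DataError(
                f"missing value(s) at row {row} (column(s) {bad_cols}); "
                "use drop_na to drop such rows"
            )
        keep = ~na_mask
        df, y_ser, cov_df = df[keep], y_ser[keep], cov_df[keep]
        logger.warning("dropped %d row(s) with missing values", int(na_mask.sum()))

    return Dataset(
        X=df[feature_cols].to_numpy(dtype=float),
        y=y_ser.to_numpy(),
        feature_names=feature_cols,
        task=task,
        covariates=cov_df.to_numpy(dtype=float) if covariate_columns else None,
        covariate_names=covariate_columns,
        target_name=target_column,
    )


def write_table(dataset: Dataset, path: str, sep: str = ",") -> None:
    """Write a dataset back to delimited text (full float precision)."""
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    if dataset.covariates is not None:
        for j, name in enumerate(dataset.covariate_names):
            df[name] = dataset.covariates[:, j]
    df[dataset.target_name] = dataset.y
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def make_split(dataset: Dataset, config: SplitConfig) -> Split:
    """Random (optionally stratified) train/test split of the dataset rows."""
    n = dataset.n
    if n < config.cv_folds * 2:
        raise DataError(f"need at least {config.cv_folds * 2} rows, got {n}")
    n_train = int(round(config.train_fraction * n))
    stratify = None
    if config.stratified:
        if dataset.task != CLASSIFICATION:
            raise DataError("stratified splitting requires a classification task")
        labels, counts = np.unique(dataset.y, return_counts=True)
        small = labels[counts < config.cv_folds]
        if small.size:
            raise DataError(
                f"class(es) {small.tolist()} have fewer than cv_folds="
                f"{config.cv_folds} members; cannot stratify"
            )
        stratify = dataset.y
    train_idx, test_idx = train_test_split(
        np.arange(n),
        train_size=n_train,
        random_state=config.seed,
        shuffle=True,
        stratify=stratify,
    )
    return Split(train_idx=np.sort(train_idx), test_idx=np.sort(test_idx))


def residualize_covariates(dataset: Dataset, split: Split) -> Dataset:
    """Replace each feature by its OLS residual on the covariates.

    The regression (with intercept) is fit on training rows only and the
    fitted coefficients are applied to every row; the returned dataset has
    no covariates. Fitting on the full data would leak test information
    into the adjustment.
    """
    if dataset.covariates is None:
        raise DataError("dataset has no covariates to residualize")
    C = np.column_stack([np.ones(dataset.n), dataset.covariates])
    C_train = C[split.train_idx]
    if np.linalg.matrix_rank(C_train) < C.shape[1]:
        raise DataError("covariate matrix is rank-deficient on training rows")
    beta, *_ = np.linalg.lstsq(C_train, dataset.X[split.train_idx], rcond=None)
    return replace(
        dataset,
        X=dataset.X - C @ beta,
        covariates=None,
        covariate_names=[],
    )
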