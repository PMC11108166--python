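"""The leakage-safe modelling pipeline fitted inside every training partition.

Stage order is fixed: mutual-information feature selection (optional) →
standardisation → random oversampling (optional) → SVM.  Every statistic the
pipeline needs — feature ranking, per-column mean and standard deviation,
oversampling draws — is computed from the training rows alone, and test rows
only ever pass through the frozen transforms.  That discipline is the entire
point of fitting the pipeline inside each cross-validation training
partition: no information from a held-out fold can leak into model fitting
or selection.

Feature ranking uses a plug-in mutual-information estimate on the
contingency table of each (discretised) feature with the label.  Continuous
features are discretised into ``min(10, #unique)`` quantile bins, which
keeps the estimator deterministic and adequate for ranking; categorical
features arrive as integer codes and bin to themselves.  Ties are broken by
lower column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.metrics import mutual_info_score

from . import _svm
from ._svm import KERNELS, SVMModel
from .exceptions import DegenerateFoldError, InvalidSpecError

__all__ = [
    "PipelineConfig",
    "FittedPipeline",
    "rank_features_mi",
    "standardise_fit",
    "standardise_apply",
    "random_oversample",
    "fit_pipeline",
    "predict",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline and ablation configuration.

    ``use_feature_selection`` and ``use_hyperparameter_tuning`` are the two
    ablation switches.  ``C``, ``gamma`` and ``kernel`` are the SVM
    hyperparameters actually used when tuning is off (the library defaults
    C=1, gamma='scale', kernel='rbf'); when tuning is on they serve as the
    starting values that grid search overrides per outer fold.
    ``n_features_to_select`` defaults to 10, the smallest value of the
    standard grid, and is the fixed count used when selection is on but
    tuning is off.  ``seed`` drives the oversampling draws.
    """

    use_feature_selection: bool = False
    use_hyperparameter_tuning: bool = True
    n_features_to_select: int = 10
    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"
    oversample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features_to_select < 1:
            raise InvalidSpecError("n_features_to_select must be >= 1")
        if not self.C > 0:
            raise InvalidSpecError(f"C must be positive, got {self.C}")
        if self.kernel not in KERNELS:
            raise InvalidSpecError(f"unknown kernel {self.kernel!r}")
        if isinstance(self.gamma, str):
            if self.gamma not in ("scale", "auto"):
                raise InvalidSpecError(f"unknown symbolic gamma {self.gamma!r}")
        elif not self.gamma > 0:
            raise InvalidSpecError(f"gamma must be positive, got {self.gamma}")

    def with_params(self, **params: Any) -> "PipelineConfig":
        """Return a copy with hyperparameters replaced (grid-search helper)."""
        return replace(self, **params)


@dataclass
class FittedPipeline:
    """Frozen state of a pipeline fitted on one training partition."""

    selected_features: np.ndarray  # column indices into the original width
    mean: np.ndarray               # per selected column, training rows only
    scale: np.ndarray              # per selected column; 1 where variance was 0
    classes: np.ndarray            # the two class codes, sorted
    model: SVMModel
    positive_class: Any
    n_features_in: int


def rank_features_mi(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank features by decreasing mutual information with the label.

    Each column is discretised into ``min(10, #unique)`` quantile bins and
    the plug-in MI of the binned column with the label is computed from the
    contingency table.  Constant columns have MI 0.  The returned index array
    is a permutation of ``range(n_features)``; equal MI breaks toward the
    lower column index, so the ranking is fully deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise DegenerateFoldError("need at least two rows to rank features")
    if len(np.unique(y)) < 2:
        raise DegenerateFoldError("single-class training data")
    mi = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        mi[j] = mutual_info_score(y, _quantile_bin(X[:, j]))
    return np.argsort(-mi, kind="stable")


def _quantile_bin(col: np.ndarray, max_bins: int = 10) -> np.ndarray:
    uniq = np.unique(col)
    if len(uniq) <= max_bins:
        return np.searchsorted(uniq, col)
    edges = np.quantile(col, np.linspace(0, 1, max_bins + 1)[1:-1])
    return np.searchsorted(edges, col)


def standardise_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and standard deviation from training rows.

    Zero-variance columns get scale 1 so they are centred but not divided;
    population (ddof=0) standard deviations are used.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise DegenerateFoldError("need at least two rows to standardise")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return mean, scale


def standardise_apply(params: tuple[np.ndarray, np.ndarray], X: np.ndarray) -> np.ndarray:
    mean, scale = params
    return (np.asarray(X, dtype=np.float64) - mean) / scale


def random_oversample(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority rows (sampled with replacement) until counts are equal.

    The original rows are kept in order, duplicates are appended, and
    already-balanced input is returned unchanged.  Test partitions are never
    oversampled.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateFoldError("single-class input cannot be oversampled")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[int(np.argmin(counts))]
    deficit = int(abs(counts[0] - counts[1]))
    pool = np.flatnonzero(y == minority)
    rng = np.random.default_rng(seed)
    extra = rng.choice(pool, size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def fit_pipeline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: PipelineConfig,
    positive_class,
    _ranking: np.ndarray | None = None,
) -> FittedPipeline:
    """Fit selection → standardisation → oversampling → SVM on training rows.

    ``_ranking`` lets grid search reuse a precomputed MI ranking for the same
    training rows (the ranking does not depend on any hyperparameter); when
    omitted it is computed here.  Selected columns are kept in original
    column order.
    """
    X_train = np.ascontiguousarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise DegenerateFoldError("single-class training partition")

    if cfg.use_feature_selection:
        if cfg.n_features_to_select > X_train.shape[1]:
            raise InvalidSpecError(
                f"cannot select {cfg.n_features_to_select} of "
                f"{X_train.shape[1]} features"
            )
        ranking = rank_features_mi(X_train, y_train) if _ranking is None else _ranking
        selected = np.sort(ranking[: cfg.n_features_to_select])
        Xs = X_train[:, selected]
    else:
        selected = np.arange(X_train.shape[1])
        Xs = X_train

    mean, scale = standardise_fit(Xs)
    Xz = (Xs - mean) / scale
    y_fit = y_train
    if cfg.oversample:
        Xz, y_fit = random_oversample(Xz, y_fit, cfg.seed)

    codes = np.ascontiguousarray(
        np.searchsorted(classes, y_fit), dtype=np.float64
    )
    model = _svm.fit_svm(
        np.ascontiguousarray(Xz), codes,
        C=cfg.C, gamma=cfg.gamma, kernel=cfg.kernel,
    )
    return FittedPipeline(
        selected_features=selected,
        mean=mean,
        scale=scale,
        classes=classes,
        model=model,
        positive_class=positive_class,
        n_features_in=X_train.shape[1],
    )


def predict(fp: FittedPipeline, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict hard labels and decision scores for test rows.

    Test rows pass through the frozen selection and standardisation; no
    oversampling is ever applied at test time.  Decision scores are oriented
    so that larger values favour ``positive_class``.
    """
    X_test = np.asarray(X_test, dtype=np.float64)
    if X_test.ndim != 2 or X_test.shape[1] != fp.n_features_in:
        raise InvalidSpecError(
            f"test width {X_test.shape[1] if X_test.ndim == 2 else '?'} does not "
            f"match training width {fp.n_features_in}"
        )
    Xz = np.ascontiguousarray(
        (X_test[:, fp.selected_features] - fp.mean) / fp.scale
    )
    codes = fp.model.predict(Xz)
    labels = fp.classes[codes]
    dec = fp.model.decision_function(Xz)  # favours class code 1
    if fp.positive_class == fp.classes[0]:
        dec = -dec
    return labels, dec
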