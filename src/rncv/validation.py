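"""Stratified folds, inner grid search, nested and repeated nested CV.

Nested cross-validation (nCV) separates model selection from model
assessment: an outer stratified n-fold CV estimates generalisation
performance, while an inner stratified k-fold CV run on each outer training
partition picks the hyperparameter combination with the best inner mean of
the chosen metric.  The winning pipeline is refitted on the whole outer
training partition and scored once on the held-out fold; the nCV score is
the mean over outer folds.  Training and evaluation always use the same
metric, and the positive class is the minority class of the full dataset.

Repeated nested CV (rnCV) re-runs the nCV under several random seeds
(different fold assignments) and averages the repeat means; by construction
the rnCV mean is exactly the arithmetic mean of its component nCV means.
On small datasets single-seed nCV scores fluctuate considerably, and the
repeat spread (min/max/sd) is itself a useful diagnostic.

Fold-count feasibility is never adjusted silently: if some class has fewer
rows than folds, :class:`~rncv.exceptions.StratificationError` is raised and
the caller chooses a smaller fold count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import _svm
from . import pipeline as _pl
from .data import Dataset, minority_class
from .exceptions import DegenerateFoldError, InvalidSpecError, StratificationError
from .metrics import ConfusionMatrix, auc, average_confusions, confusion, score
from .pipeline import PipelineConfig

__all__ = [
    "SVM_GRID",
    "SVM_FS_GRID",
    "FoldPlan",
    "NCVResult",
    "RNCVResult",
    "stratified_folds",
    "grid_combinations",
    "grid_search",
    "nested_cv",
    "repeated_nested_cv",
    "train_test_split_eval",
    "ablation_variants",
    "derive_seed",
]

#: The standard SVM hyperparameter grid (36 combinations).
SVM_GRID: dict[str, list] = {
    "C": [0.1, 1, 10],
    "gamma": [0.1, "scale", "auto"],
    "kernel": ["linear", "rbf", "poly", "sigmoid"],
}

#: The standard grid extended with the feature-selection count (180 combinations).
SVM_FS_GRID: dict[str, list] = {
    **SVM_GRID,
    "n_features_to_select": [10, 15, 20, 25, 30],
}

#: Default fold and repeat counts.
DEFAULT_OUTER_FOLDS = 10
DEFAULT_INNER_FOLDS = 5
DEFAULT_REPEATS = 5
DEFAULT_TRAIN_FRACTION = 0.8


def derive_seed(*parts: int) -> int:
    """Deterministically derive a 31-bit child seed from integer parts."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of rows into ``k`` folds."""

    k: int
    assignments: np.ndarray  # fold index per row
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of the training and test partitions of one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test

    def __iter__(self):
        return (self.split(i) for i in range(self.k))


@dataclass
class NCVResult:
    """Result of one nested cross-validation run."""

    fold_scores: np.ndarray
    mean_score: float
    chosen_params: list[dict | None]
    confusions: list[ConfusionMatrix]
    metric: str
    seed: int


@dataclass
class RNCVResult:
    """Result of a repeated nested cross-validation (one :class:`NCVResult` per seed)."""

    ncvs: list[NCVResult]
    mean_score: float
    score_min: float
    score_max: float
    score_sd: float
    averaged_confusion: ConfusionMatrix

    @property
    def repeat_scores(self) -> np.ndarray:
        return np.array([r.mean_score for r in self.ncvs])


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Assign rows to ``k`` folds with per-fold class proportions matching the data.

    Within each class the rows are shuffled with the seeded RNG and dealt
    round-robin to folds; a running cursor carries across classes so total
    fold sizes differ by at most one.  Requires every class count >= ``k``
    so each fold holds at least one row of each class.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidSpecError(f"fold count must be >= 2, got {k}")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} rows; cannot stratify into {k} folds"
        )
    rng = np.random.default_rng(seed)
    assignments = np.empty(labels.shape[0], dtype=np.int64)
    cursor = 0
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for row in idx:
            assignments[row] = cursor % k
            cursor += 1
    return FoldPlan(k=k, assignments=assignments, seed=int(seed))


def grid_combinations(grid: Mapping[str, Sequence[Any]]) -> list[dict[str, Any]]:
    """All hyperparameter combinations, in declared order (first key varies slowest)."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise InvalidSpecError("grid must have at least one value per parameter")
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*grid.values())]


def _fold_eval(fp, X_te, y_te_pos, dec_needed, y_te, positive_class, metric):
    """Score one fitted pipeline on one test fold (hot path)."""
    Xz = np.ascontiguousarray(
        (X_te[:, fp.selected_features] - fp.mean) / fp.scale
    )
    if dec_needed:
        dec = fp.model.decision_function(Xz)
        if fp.positive_class == fp.classes[0]:
            dec = -dec
        return auc(y_te, dec, positive_class)
    codes = fp.model.predict(Xz)
    pred_pos = fp.classes[codes] == positive_class
    tp = int(np.count_nonzero(y_te_pos & pred_pos))
    fp_ = int(np.count_nonzero(~y_te_pos & pred_pos))
    fn = int(np.count_nonzero(y_te_pos & ~pred_pos))
    tn = int(np.count_nonzero(~y_te_pos & ~pred_pos))
    return score(metric, ConfusionMatrix(tp, fp_, fn, tn))


def grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: Mapping[str, Sequence[Any]],
    k_inner: int,
    metric: str,
    cfg: PipelineConfig,
    seed: int,
    positive_class=None,
) -> tuple[dict[str, Any], np.ndarray]:
    """Exhaustive inner-CV search over ``grid``.

    Each combination is scored by the stratified ``k_inner``-fold CV mean of
    ``metric``, with the full pipeline fitted per inner fold.  Returns the
    winning combination (ties break toward the first combination in declared
    grid order) together with the inner mean score of every combination.
    """
    X_train = np.ascontiguousarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if positive_class is None:
        positive_class = minority_class(y_train)
    plan = stratified_folds(y_train, k_inner, seed)
    combos = grid_combinations(grid)
    if not cfg.use_feature_selection:
        return _grid_search_fixed_features(
            X_train, y_train, plan, combos, metric, cfg, positive_class)

    folds = []
    for tr, te in plan:
        X_tr = np.ascontiguousarray(X_train[tr])
        y_tr = y_train[tr]
        X_te = X_train[te]
        y_te = y_train[te]
        ranking = _pl.rank_features_mi(X_tr, y_tr)
        folds.append((X_tr, y_tr, X_te, y_te, y_te == positive_class, ranking))

    dec_needed = metric == "auc"
    inner_means = np.empty(len(combos))
    best_idx, best_score = 0, -np.inf
    for c, combo in enumerate(combos):
        cfg_c = cfg.with_params(**combo)
        total = 0.0
        for X_tr, y_tr, X_te, y_te, y_te_pos, ranking in folds:
            fp = _pl.fit_pipeline(X_tr, y_tr, cfg_c, positive_class, _ranking=ranking)
            total += _fold_eval(fp, X_te, y_te_pos, dec_needed, y_te,
                                positive_class, metric)
        inner_means[c] = total / len(folds)
        if inner_means[c] > best_score:
            best_idx, best_score = c, inner_means[c]
    return combos[best_idx], inner_means


def _grid_search_fixed_features(X_train, y_train, plan, combos, metric, cfg,
                                positive_class):
    """Grid-search fast path when feature selection is off.

    Standardisation, oversampling and label encoding do not depend on any
    hyperparameter in the grid, so they are computed once per inner fold and
    only the SVM fit runs per combination.  Results are exactly those of
    fitting the full pipeline per combination (asserted in the test suite);
    this matters because an ensemble study performs millions of inner fits.
    """
    classes = np.unique(y_train)
    pos_code = int(np.searchsorted(classes, positive_class))
    dec_needed = metric == "auc"
    folds = []
    for tr, te in plan:
        X_tr, y_tr = X_train[tr], y_train[tr]
        mean, scale = _pl.standardise_fit(X_tr)
        Xz_tr = (X_tr - mean) / scale
        y_fit = y_tr
        if cfg.oversample:
            Xz_tr, y_fit = _pl.random_oversample(Xz_tr, y_fit, cfg.seed)
        codes = np.ascontiguousarray(np.searchsorted(classes, y_fit),
                                     dtype=np.float64)
        Xz_te = np.ascontiguousarray((X_train[te] - mean) / scale)
        y_te = y_train[te]
        folds.append((np.ascontiguousarray(Xz_tr), codes, Xz_te, y_te,
                      y_te == positive_class))

    inner_means = np.empty(len(combos))
    best_idx, best_score = 0, -np.inf
    for c, combo in enumerate(combos):
        total = 0.0
        for Xz_tr, codes, Xz_te, y_te, y_te_pos in folds:
            model = _svm.fit_svm(Xz_tr, codes,
                            C=combo.get("C", cfg.C),
                            gamma=combo.get("gamma", cfg.gamma),
                            kernel=combo.get("kernel", cfg.kernel))
            if dec_needed:
                dec = model.decision_function(Xz_te)
                if pos_code == 0:
                    dec = -dec
                total += auc(y_te, dec, positive_class)
            else:
                pred_pos = model.predict(Xz_te) == pos_code
                tp = int(np.count_nonzero(y_te_pos & pred_pos))
                fp_ = int(np.count_nonzero(~y_te_pos & pred_pos))
                fn = int(np.count_nonzero(y_te_pos & ~pred_pos))
                tn = int(np.count_nonzero(~y_te_pos & ~pred_pos))
                total += score(metric, ConfusionMatrix(tp, fp_, fn, tn))
        inner_means[c] = total / len(folds)
        if inner_means[c] > best_score:
            best_idx, best_score = c, inner_means[c]
    return combos[best_idx], inner_means


def nested_cv(
    ds: Dataset,
    cfg: PipelineConfig,
    grid: Mapping[str, Sequence[Any]] | None = None,
    metric: str = "mcc",
    n_outer: int = DEFAULT_OUTER_FOLDS,
    k_inner: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
) -> NCVResult:
    """One nested cross-validation run under one seed.

    Per outer fold: grid search on the outer training partition (skipped
    entirely when ``cfg.use_hyperparameter_tuning`` is off, in which case the
    configured defaults are used and no inner CV runs), refit of the winning
    pipeline on the whole outer training partition, and a single evaluation
    on the held-out fold.  The seed governs both fold assignments and the
    stochastic pipeline stages of the run.
    """
    if grid is None:
        grid = SVM_FS_GRID if cfg.use_feature_selection else SVM_GRID
    positive = minority_class(ds.labels)
    cfg = replace(cfg, seed=int(seed))
    X = np.ascontiguousarray(ds.features)
    y = ds.labels
    plan = stratified_folds(y, n_outer, seed)

    fold_scores = np.empty(n_outer)
    chosen: list[dict | None] = []
    cms: list[ConfusionMatrix] = []
    for i, (tr, te) in enumerate(plan):
        X_tr, y_tr = np.ascontiguousarray(X[tr]), y[tr]
        X_te, y_te = X[te], y[te]
        if cfg.use_hyperparameter_tuning:
            inner_seed = derive_seed(seed, i)
            best, _ = grid_search(X_tr, y_tr, grid, k_inner, metric, cfg,
                                  inner_seed, positive)
            cfg_i = cfg.with_params(**best)
            chosen.append(best)
        else:
            cfg_i = cfg
            chosen.append(None)
        fp = _pl.fit_pipeline(X_tr, y_tr, cfg_i, positive)
        labels, dec = _pl.predict(fp, X_te)
        cm = confusion(y_te, labels, positive)
        cms.append(cm)
        fold_scores[i] = (auc(y_te, dec, positive) if metric == "auc"
                          else score(metric, cm))
    return NCVResult(
        fold_scores=fold_scores,
        mean_score=float(np.mean(fold_scores)),
        chosen_params=chosen,
        confusions=cms,
        metric=metric,
        seed=int(seed),
    )


def repeated_nested_cv(
    ds: Dataset,
    cfg: PipelineConfig,
    grid: Mapping[str, Sequence[Any]] | None = None,
    metric: str = "mcc",
    n_outer: int = DEFAULT_OUTER_FOLDS,
    k_inner: int = DEFAULT_INNER_FOLDS,
    repeat_seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> RNCVResult:
    """Repeat :func:`nested_cv` under each seed and aggregate.

    The rnCV mean is the arithmetic mean of the repeat means (an exact
    identity, not an approximation); min/max/sd describe the repeat spread,
    and the averaged confusion matrix pools all outer folds of all repeats.
    """
    if not repeat_seeds:
        raise InvalidSpecError("repeat_seeds must be non-empty")
    ncvs = [nested_cv(ds, cfg, grid, metric, n_outer, k_inner, s)
            for s in repeat_seeds]
    means = np.array([r.mean_score for r in ncvs])
    all_cms = [cm for r in ncvs for cm in r.confusions]
    return RNCVResult(
        ncvs=ncvs,
        mean_score=float(np.mean(means)),
        score_min=float(means.min()),
        score_max=float(means.max()),
        score_sd=float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
        averaged_confusion=average_confusions(all_cms),
    )


def train_test_split_eval(
    ds: Dataset,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    cfg: PipelineConfig | None = None,
    grid: Mapping[str, Sequence[Any]] | None = None,
    metric: str = "mcc",
    seed: int = 0,
) -> float:
    """Single stratified train/test split, scored once on the test part.

    When tuning is on, hyperparameters are chosen by the inner CV on the
    training part before the final fit.  The score of this method varies
    strongly with the seed on small datasets, which is precisely why the
    repeated nested design exists.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if not 0.0 < train_fraction < 1.0:
        raise InvalidSpecError("train_fraction must be in (0, 1)")
    if grid is None:
        grid = SVM_FS_GRID if cfg.use_feature_selection else SVM_GRID
    positive = minority_class(ds.labels)
    cfg = replace(cfg, seed=int(seed))
    idx_tr, idx_te = train_test_split(
        np.arange(ds.n_points),
        train_size=train_fraction,
        random_state=int(seed) & 0x7FFFFFFF,
        stratify=ds.labels,
    )
    X_tr, y_tr = ds.features[idx_tr], ds.labels[idx_tr]
    X_te, y_te = ds.features[idx_te], ds.labels[idx_te]
    for part in (y_tr, y_te):
        if len(np.unique(part)) < 2:
            raise DegenerateFoldError("a split partition lost one class")
    if cfg.use_hyperparameter_tuning:
        best, _ = grid_search(X_tr, y_tr, grid, DEFAULT_INNER_FOLDS, metric,
                              cfg, derive_seed(seed, 0), positive)
        cfg = cfg.with_params(**best)
    fp = _pl.fit_pipeline(X_tr, y_tr, cfg, positive)
    labels, dec = _pl.predict(fp, X_te)
    if metric == "auc":
        return float(auc(y_te, dec, positive))
    return float(score(metric, confusion(y_te, labels, positive)))


def ablation_variants(base_cfg: PipelineConfig) -> dict[str, PipelineConfig]:
    """The four ablation configurations of the evaluation pipeline.

    ``full`` enables both feature selection and hyperparameter tuning,
    ``no_feature_selection`` and ``no_hyperparameter_tuning`` each switch one
    off, and ``neither`` switches off both (no inner CV runs at all).  All
    other settings are inherited from ``base_cfg``.
    """
    return {
        "full": replace(base_cfg, use_feature_selection=True,
                        use_hyperparameter_tuning=True),
        "no_feature_selection": replace(base_cfg, use_feature_selection=False,
                                        use_hyperparameter_tuning=True),
        "no_hyperparameter_tuning": replace(base_cfg, use_feature_selection=True,
                                            use_hyperparameter_tuning=False),
        "neither": replace(base_cfg, use_feature_selection=False,
                           use_hyperparameter_tuning=False),
    }
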