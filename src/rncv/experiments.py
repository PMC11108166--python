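"""Ensemble studies: size sweeps, metric comparisons, ablations, bootstrap CIs.

These orchestrators reproduce the structure of the simulation studies: many
synthetic datasets per size, a shared-permutation test per dataset, and
ensemble summaries (mean normalised score, mean null-hypothesis probability)
with percentile-bootstrap 95% confidence intervals over datasets.  All
outputs are tidy :class:`pandas.DataFrame` tables, optionally flushed to CSV
as they grow so partial results survive interruption.

All permutation counts of a sweep are evaluated on the same datasets and the
same permutations (probabilities for a smaller N use the first N permuted
scores), which removes between-N sampling noise from the comparison.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, GeneratorSpec, generate_ensemble, permute_labels
from .exceptions import InvalidSpecError
from .metrics import normalise
from .permutation import PermutationResult, _assemble, empirical_probability
from .pipeline import PipelineConfig
from .validation import (
    DEFAULT_INNER_FOLDS,
    DEFAULT_OUTER_FOLDS,
    SVM_GRID,
    ablation_variants,
    derive_seed,
    repeated_nested_cv,
)

__all__ = [
    "SweepSpec",
    "bootstrap_ci",
    "run_sweep",
    "run_ablation",
    "compare_metrics_report",
    "ncv_vs_rncv_ensemble",
]

logger = logging.getLogger("rncv")


@dataclass
class SweepSpec:
    """Configuration of an ensemble sweep over dataset sizes.

    Defaults mirror the standard simulation conditions: 10-feature balanced
    Gaussian datasets with a 0.2 mean shift, MCC evaluation with the
    36-combination SVM grid (no feature selection — the synthetic features
    are exchangeable by construction), 10-fold outer and 5-fold inner CV,
    5 repeats, and 25 permutations.
    """

    sizes: Sequence[int]
    datasets_per_size: int = 10
    metrics: Sequence[str] = ("mcc",)
    permutation_counts: Sequence[int] = (25,)
    grid: Mapping[str, Sequence[Any]] = field(default_factory=lambda: dict(SVM_GRID))
    outer_folds: int = DEFAULT_OUTER_FOLDS
    inner_folds: int = DEFAULT_INNER_FOLDS
    repeats: int = 5
    n_features: int = 10
    class2_mean: float = 0.2
    master_seed: int = 0
    out: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.sizes or not self.metrics or not self.permutation_counts:
            raise InvalidSpecError("sizes, metrics and permutation_counts must be non-empty")


def bootstrap_ci(
    values, level: float = 0.95, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean.

    Draws ``n_boot`` resamples with replacement and returns the
    ``(1-level)/2`` and ``1-(1-level)/2`` quantiles of the resampled means.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InvalidSpecError("cannot bootstrap an empty sample")
    if n_boot < 1:
        raise InvalidSpecError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _dataset_permutation_run(
    ds: Dataset,
    cfg: PipelineConfig,
    grid,
    metrics: Sequence[str],
    n_outer: int,
    k_inner: int,
    repeat_seeds: Sequence[int],
    n_permutations: int,
    seed: int,
) -> dict[str, PermutationResult]:
    """One dataset, one shared set of permutations, one result per metric."""
    perm_seeds = np.random.default_rng(seed).integers(0, 2**31, size=n_permutations)
    permuted = [permute_labels(ds, int(s)) for s in perm_seeds]
    out = {}
    for metric in metrics:
        original = repeated_nested_cv(ds, cfg, grid, metric, n_outer, k_inner,
                                      repeat_seeds)
        perm_results = [repeated_nested_cv(p, cfg, grid, metric, n_outer,
                                           k_inner, repeat_seeds)
                        for p in permuted]
        out[metric] = _assemble(metric, original, perm_results, perm_seeds)
    return out


def run_sweep(spec: SweepSpec, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the full ensemble sweep and return one row per (size, metric, N).

    Columns: dataset size, metric, permutation count, number of datasets,
    mean normalised score with bootstrap CI, and mean probability with
    bootstrap CI.  Deterministic given ``spec.master_seed``; when
    ``spec.out`` is set the table is rewritten after every size so partial
    results are preserved on interruption.
    """
    if cfg is None:
        cfg = PipelineConfig(use_feature_selection=False,
                             use_hyperparameter_tuning=True)
    template = GeneratorSpec(n_points=2, n_features=spec.n_features,
                             class2_mean=spec.class2_mean)
    n_max = max(spec.permutation_counts)
    rows: list[dict] = []
    for si, size in enumerate(spec.sizes):
        t0 = time.perf_counter()
        datasets = generate_ensemble(
            [size], spec.datasets_per_size, template,
            seed=derive_seed(spec.master_seed, 1, si),
        )
        # per (metric, N): one normalised score and one probability per dataset
        scores: dict[tuple, list[float]] = {}
        probs: dict[tuple, list[float]] = {}
        for di, ds in enumerate(datasets):
            run_seed = derive_seed(spec.master_seed, 2, si, di)
            repeat_seeds = [derive_seed(run_seed, 3, r) for r in range(spec.repeats)]
            results = _dataset_permutation_run(
                ds, cfg, spec.grid, spec.metrics, spec.outer_folds,
                spec.inner_folds, repeat_seeds, n_max, derive_seed(run_seed, 4),
            )
            for metric, res in results.items():
                perm_means = [p.mean_score for p in res.permuted]
                for n_perm in spec.permutation_counts:
                    p = empirical_probability(res.original.mean_score,
                                              perm_means[:n_perm])
                    key = (metric, n_perm)
                    scores.setdefault(key, []).append(
                        normalise(metric, res.original.mean_score))
                    probs.setdefault(key, []).append(p)
        for metric in spec.metrics:
            for n_perm in spec.permutation_counts:
                key = (metric, n_perm)
                s, p = np.array(scores[key]), np.array(probs[key])
                ci_seed = derive_seed(spec.master_seed, 5, si)
                s_lo, s_hi = bootstrap_ci(s, seed=ci_seed)
                p_lo, p_hi = bootstrap_ci(p, seed=ci_seed)
                rows.append({
                    "size": size, "metric": metric, "n_permutations": n_perm,
                    "n_datasets": len(datasets),
                    "mean_score": s.mean(), "score_ci_low": s_lo,
                    "score_ci_high": s_hi,
                    "mean_probability": p.mean(), "probability_ci_low": p_lo,
                    "probability_ci_high": p_hi,
                })
        logger.info("sweep size=%d done in %.1fs", size, time.perf_counter() - t0)
        if spec.out is not None:
            pd.DataFrame(rows).to_csv(spec.out, index=False)
    return pd.DataFrame(rows)


def ncv_vs_rncv_ensemble(
    n_points: int = 50,
    n_datasets: int = 10,
    metric: str = "mcc",
    n_permutations: int = 25,
    repeats: int = 5,
    cfg: PipelineConfig | None = None,
    grid: Mapping[str, Sequence[Any]] | None = None,
    n_outer: int = DEFAULT_OUTER_FOLDS,
    k_inner: int = DEFAULT_INNER_FOLDS,
    n_features: int = 10,
    class2_mean: float = 0.2,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Shared-permutation test over an ensemble of synthetic datasets.

    Generates ``n_datasets`` balanced Gaussian datasets of ``n_points`` rows,
    runs the permutation test on each (rnCV with ``repeats`` repeats against
    ``n_permutations`` shared permutations), and returns one row per dataset
    with the rnCV score, the rnCV probability, and the averaged per-seed nCV
    probability.  This is the study design used both for the
    probability-versus-size curves and for contrasting the rnCV and nCV
    probability calculations on identical permutations.
    """
    if cfg is None:
        cfg = PipelineConfig(use_feature_selection=False,
                             use_hyperparameter_tuning=True)
    if grid is None:
        grid = SVM_GRID
    template = GeneratorSpec(n_points=2, n_features=n_features,
                             class2_mean=class2_mean)
    datasets = generate_ensemble([n_points], n_datasets, template,
                                 seed=derive_seed(master_seed, 1))
    rows = []
    for di, ds in enumerate(datasets):
        t0 = time.perf_counter()
        run_seed = derive_seed(master_seed, 2, di)
        repeat_seeds = [derive_seed(run_seed, 3, r) for r in range(repeats)]
        res = _dataset_permutation_run(
            ds, cfg, grid, [metric], n_outer, k_inner, repeat_seeds,
            n_permutations, derive_seed(run_seed, 4),
        )[metric]
        rows.append({
            "dataset": di, "n_points": n_points, "metric": metric,
            "score": res.original.mean_score,
            "score_sd": res.original.score_sd,
            "p_rncv": res.p_rncv,
            "p_ncv_averaged": res.p_ncv_averaged,
        })
        logger.info("ensemble dataset %d/%d done in %.1fs",
                    di + 1, n_datasets, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def run_ablation(
    ds: Dataset,
    base_cfg: PipelineConfig,
    metric: str = "mcc",
    n_permutations: int = 50,
    repeat_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    grid: Mapping[str, Sequence[Any]] | None = None,
    n_outer: int = DEFAULT_OUTER_FOLDS,
    k_inner: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Score and probability for the four ablation variants of the pipeline.

    All four variants (full / no feature selection / no hyperparameter
    tuning / neither) are evaluated against the same permuted label sets, so
    their probabilities are directly comparable.
    """
    perm_seeds = np.random.default_rng(seed).integers(0, 2**31, size=n_permutations)
    permuted = [permute_labels(ds, int(s)) for s in perm_seeds]
    rows = []
    for name, cfg in ablation_variants(base_cfg).items():
        t0 = time.perf_counter()
        original = repeated_nested_cv(ds, cfg, grid, metric, n_outer, k_inner,
                                      repeat_seeds)
        perm_results = [repeated_nested_cv(p, cfg, grid, metric, n_outer,
                                           k_inner, repeat_seeds)
                        for p in permuted]
        res = _assemble(metric, original, perm_results, perm_seeds)
        rows.append({
            "variant": name, "metric": metric,
            "score": original.mean_score,
            "probability": res.p_rncv,
        })
        logger.info("ablation %s done in %.1fs", name, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def compare_metrics_report(
    ds: Dataset,
    metrics: Sequence[str],
    cfg: PipelineConfig | None = None,
    n_permutations: int = 50,
    repeat_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    grid: Mapping[str, Sequence[Any]] | None = None,
    n_outer: int = DEFAULT_OUTER_FOLDS,
    k_inner: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """One rnCV + permutation test per metric, sharing folds and permutations.

    Each metric is used for both training (inner-CV selection) and
    evaluation.  Returns one row per metric with the raw and normalised
    score, the rnCV and averaged-nCV probabilities, and the averaged
    confusion-matrix entries.
    """
    if cfg is None:
        cfg = PipelineConfig()
    results = _dataset_permutation_run(
        ds, cfg, grid, metrics, n_outer, k_inner, repeat_seeds,
        n_permutations, seed,
    )
    rows = []
    for metric, res in results.items():
        cm = res.original.averaged_confusion
        rows.append({
            "metric": metric,
            "score": res.original.mean_score,
            "normalised_score": normalise(metric, res.original.mean_score),
            "score_sd": res.original.score_sd,
            "p_rncv": res.p_rncv,
            "p_ncv_averaged": res.p_ncv_averaged,
            "cm_tp": cm.tp, "cm_fp": cm.fp, "cm_fn": cm.fn, "cm_tn": cm.tn,
        })
    return pd.DataFrame(rows)
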