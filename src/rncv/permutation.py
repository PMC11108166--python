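"""Shared-permutation significance test for cross-validated classifiers.

The test estimates the probability that the null hypothesis — no exploitable
dependency between features and labels — is true, by re-running the complete
evaluation (repeated nested CV, including all model selection) on datasets
whose labels have been uniformly permuted.  The empirical probability uses
the add-one construction

    p = (1 + #{permuted scores >= original score}) / (1 + N),

so the smallest attainable value is ``1/(N+1)`` (2% at two decimals for
N=50) and ties count conservatively against the original.  Qualitative
comparisons are meaningful at small N, but for publication-grade p-values at
least 999 permutations should be used.

The same N permuted label vectors feed three probability estimates:

* ``p_rncv`` compares the original rnCV mean against the N permuted rnCV
  means;
* ``p_ncv_per_seed[j]`` compares the original j-th nCV score against the N
  permuted j-th nCV scores (one estimate per repeat seed);
* ``p_ncv_averaged`` is the mean of the per-seed probabilities.

Because the permutations are shared, any difference between the rnCV and
nCV probabilities is due to the aggregation method alone, not to chance:
averaging repeats before comparison shrinks the variance of both sides, so
individual permutations beat the original less often and the rnCV
probability is systematically the smaller (i.e. more powerful) one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np

from .data import Dataset, permute_labels
from .exceptions import InvalidSpecError
from .pipeline import PipelineConfig
from .validation import (
    DEFAULT_INNER_FOLDS,
    DEFAULT_OUTER_FOLDS,
    RNCVResult,
    repeated_nested_cv,
)

__all__ = [
    "PermutationResult",
    "empirical_probability",
    "permutation_test",
    "compare_ncv_vs_rncv",
]


@dataclass
class PermutationResult:
    """Original and permuted evaluations plus the derived probabilities."""

    metric: str
    original: RNCVResult
    permuted: list[RNCVResult]
    p_rncv: float
    p_ncv_per_seed: np.ndarray
    p_ncv_averaged: float
    n_permutations: int
    permutation_seeds: np.ndarray


def empirical_probability(original_score: float, permuted_scores) -> float:
    """Add-one empirical probability that the null hypothesis is true.

    ``(1 + #{s >= original}) / (1 + N)``; never zero, and ties count
    against the original.
    """
    permuted_scores = np.asarray(permuted_scores, dtype=np.float64)
    if permuted_scores.size == 0:
        raise InvalidSpecError("permuted_scores must be non-empty")
    n_ge = int(np.count_nonzero(permuted_scores >= original_score))
    return (1 + n_ge) / (1 + permuted_scores.size)


def permutation_test(
    ds: Dataset,
    cfg: PipelineConfig,
    grid: Mapping[str, Sequence[Any]] | None = None,
    metric: str = "mcc",
    n_outer: int = DEFAULT_OUTER_FOLDS,
    k_inner: int = DEFAULT_INNER_FOLDS,
    repeat_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_permutations: int = 25,
    seed: int = 0,
    permuted_datasets: Sequence[Dataset] | None = None,
) -> PermutationResult:
    """Run the shared-permutation test on one dataset.

    N label-permuted copies of the dataset are generated once (whole-dataset
    permutation, before any CV split) and each is evaluated with exactly the
    same repeat seeds and fold machinery as the original.  Permutation
    preserves class counts, so the minority/positive class and fold
    feasibility carry over unchanged.

    ``permuted_datasets`` lets callers share one set of permuted datasets
    across several evaluations (different metrics, ablation variants, or
    permutation counts); when given, ``n_permutations`` and ``seed`` are
    ignored for dataset generation.
    """
    if permuted_datasets is None:
        if n_permutations < 1:
            raise InvalidSpecError("n_permutations must be >= 1")
        perm_seeds = np.random.default_rng(seed).integers(
            0, 2**31, size=n_permutations
        )
        permuted_datasets = [permute_labels(ds, int(s)) for s in perm_seeds]
    else:
        permuted_datasets = list(permuted_datasets)
        perm_seeds = np.array([p.seed if p.seed is not None else -1
                               for p in permuted_datasets])
        n_permutations = len(permuted_datasets)

    original = repeated_nested_cv(ds, cfg, grid, metric, n_outer, k_inner,
                                  repeat_seeds)
    permuted = [repeated_nested_cv(p, cfg, grid, metric, n_outer, k_inner,
                                   repeat_seeds)
                for p in permuted_datasets]
    return _assemble(metric, original, permuted, perm_seeds)


def _assemble(
    metric: str,
    original: RNCVResult,
    permuted: list[RNCVResult],
    perm_seeds: np.ndarray,
) -> PermutationResult:
    """Compute all shared-permutation probabilities from finished evaluations."""
    perm_rncv_means = [p.mean_score for p in permuted]
    p_rncv = empirical_probability(original.mean_score, perm_rncv_means)
    n_repeats = len(original.ncvs)
    p_ncv = np.array([
        empirical_probability(
            original.ncvs[j].mean_score,
            [p.ncvs[j].mean_score for p in permuted],
        )
        for j in range(n_repeats)
    ])
    return PermutationResult(
        metric=metric,
        original=original,
        permuted=permuted,
        p_rncv=p_rncv,
        p_ncv_per_seed=p_ncv,
        p_ncv_averaged=float(p_ncv.mean()),
        n_permutations=len(permuted),
        permutation_seeds=np.asarray(perm_seeds),
    )


def compare_ncv_vs_rncv(result: PermutationResult) -> dict[str, float]:
    """Summarise one dataset's rnCV-vs-nCV comparison.

    Returns the rnCV probability, the averaged nCV probability, and the
    min/max/sd of the per-seed nCV scores — the per-dataset summary used to
    contrast the two aggregation methods.
    """
    return {
        "metric": result.metric,
        "score": result.original.mean_score,
        "score_min": result.original.score_min,
        "score_max": result.original.score_max,
        "score_sd": result.original.score_sd,
        "p_rncv": result.p_rncv,
        "p_ncv_averaged": result.p_ncv_averaged,
    }
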