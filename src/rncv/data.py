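"""Datasets: synthetic two-class Gaussian generation and tabular I/O.

The synthetic generator produces the balanced binary datasets used in the
simulation studies: the first class draws every feature i.i.d. from
``N(class1_mean, stddev**2)`` (default ``N(0, 1)``), the second class from the
same distribution with its mean shifted to ``class2_mean`` (default 0.2), and
the rows are then shuffled.  With the default 10 features and a mean shift of
0.2 the two classes overlap heavily, which is exactly what makes these
datasets useful for studying evaluation methodology: a classifier can do
better than chance, but only somewhat, and small samples make the achievable
score noisy.

Real tabular data enters through :func:`load_tabular_csv`, which requires a
declared kind (``numeric`` or ``categorical``) per feature column and exactly
two label values.  Categorical columns are encoded as integer codes at load
time and can be expanded to indicator columns with :func:`one_hot_encode`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError, LabelArityError, MissingValueError

__all__ = [
    "GeneratorSpec",
    "Dataset",
    "generate_balanced_gaussian",
    "generate_ensemble",
    "load_tabular_csv",
    "save_tabular_csv",
    "one_hot_encode",
    "minority_class",
    "permute_labels",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the balanced two-class Gaussian generator.

    Parameters
    ----------
    n_points
        Total dataset size ``n``; the first class receives ``n // 2`` rows and
        the second class the remainder.
    n_features
        Feature dimensionality (default 10).
    class1_mean, class2_mean
        Per-feature means of the two classes (defaults 0 and 0.2).
    stddev
        Common per-feature standard deviation (default 1).
    seed
        Seed of the RNG that draws features and shuffles rows; identical
        seeds yield bit-identical datasets.
    """

    n_points: int
    n_features: int = 10
    class1_mean: float = 0.0
    class2_mean: float = 0.2
    stddev: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidSpecError(f"n_points must be >= 2, got {self.n_points}")
        if self.n_features < 1:
            raise InvalidSpecError(f"n_features must be >= 1, got {self.n_features}")
        if not self.stddev > 0:
            raise InvalidSpecError(f"stddev must be > 0, got {self.stddev}")


@dataclass
class Dataset:
    """A binary-classification dataset.

    ``features`` is an ``(n, d)`` float matrix, ``labels`` a length-``n``
    vector with exactly two distinct values, and ``column_kinds`` tags each
    column as ``numeric`` or ``categorical``.  Construction validates the
    shape agreement and the two-class requirement; every downstream operation
    in the package assumes both.
    """

    features: np.ndarray
    labels: np.ndarray
    column_kinds: list[str] = field(default_factory=list)
    name: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise InvalidSpecError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise InvalidSpecError(
                f"row count mismatch: {self.features.shape[0]} feature rows "
                f"vs {self.labels.shape[0]} labels"
            )
        if not self.column_kinds:
            self.column_kinds = [NUMERIC] * self.features.shape[1]
        if len(self.column_kinds) != self.features.shape[1]:
            raise InvalidSpecError("column_kinds length must equal feature count")
        unknown = set(self.column_kinds) - {NUMERIC, CATEGORICAL}
        if unknown:
            raise InvalidSpecError(f"unknown column kinds: {sorted(unknown)}")
        if len(np.unique(self.labels)) != 2:
            raise LabelArityError(
                f"dataset must contain exactly two classes, "
                f"got {len(np.unique(self.labels))}"
            )

    @property
    def n_points(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """The two class codes in sorted order."""
        return np.unique(self.labels)


def generate_balanced_gaussian(spec: GeneratorSpec) -> Dataset:
    """Generate one balanced two-class Gaussian dataset.

    Class 1 receives ``floor(n/2)`` rows, class 2 the remainder (identical
    for even ``n``; class 2 one larger for odd ``n``).  All features of a
    class are i.i.d. Gaussian with that class's mean, and the assembled rows
    are shuffled with the same seeded RNG.  Labels are the integers 1 and 2.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = spec.n_points // 2
    n2 = spec.n_points - n1
    x1 = rng.normal(spec.class1_mean, spec.stddev, size=(n1, spec.n_features))
    x2 = rng.normal(spec.class2_mean, spec.stddev, size=(n2, spec.n_features))
    features = np.vstack([x1, x2])
    labels = np.concatenate([np.full(n1, 1), np.full(n2, 2)])
    order = rng.permutation(spec.n_points)
    name = f"gaussian-n{spec.n_points}-d{spec.n_features}-seed{spec.seed}"
    return Dataset(features[order], labels[order], [NUMERIC] * spec.n_features,
                   name=name, seed=spec.seed)


def generate_ensemble(
    sizes: Sequence[int],
    count_per_size: int,
    spec_template: GeneratorSpec | None = None,
    seed: int = 0,
) -> list[Dataset]:
    """Generate ``len(sizes) * count_per_size`` datasets with derived seeds.

    Every dataset draws its own child seed from a generator seeded with the
    master ``seed``, so the full ensemble is reproducible from one integer
    and replicates at the same size are mutually independent.
    """
    if not sizes:
        raise InvalidSpecError("sizes must be non-empty")
    if count_per_size < 1:
        raise InvalidSpecError("count_per_size must be >= 1")
    if spec_template is None:
        spec_template = GeneratorSpec(n_points=2)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31, size=len(sizes) * count_per_size)
    out = []
    i = 0
    for size in sizes:
        for _ in range(count_per_size):
            spec = replace(spec_template, n_points=int(size), seed=int(child_seeds[i]))
            out.append(generate_balanced_gaussian(spec))
            i += 1
    return out


def load_tabular_csv(
    path: str | Path,
    label_column: str = "label",
    column_kinds: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> Dataset:
    """Load a delimited text file into a :class:`Dataset`.

    ``column_kinds`` maps feature column names to ``numeric`` or
    ``categorical``; unlisted columns default to numeric.  When the argument
    is omitted and a sidecar schema written by :func:`save_tabular_csv`
    exists next to the file, the sidecar is used.  Categorical values are
    replaced by integer codes in sorted-value order.  Missing cells are
    rejected rather than imputed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise MissingValueError(f"label column {label_column!r} not in {list(df.columns)}")
    if column_kinds is None:
        sidecar = path.with_suffix(path.suffix + ".schema")
        column_kinds = _read_schema(sidecar) if sidecar.exists() else {}
    na = df.isna()
    if na.to_numpy().any():
        row = int(na.any(axis=1).idxmax())
        col = na.columns[na.loc[row].to_numpy().argmax()]
        raise MissingValueError(f"missing value at row {row}, column {col!r}")
    labels = df[label_column].to_numpy()
    if len(np.unique(labels)) != 2:
        raise LabelArityError(
            f"label column {label_column!r} has {len(np.unique(labels))} "
            "distinct values; exactly two are required"
        )
    feature_cols = [c for c in df.columns if c != label_column]
    kinds, columns = [], []
    for col in feature_cols:
        kind = column_kinds.get(col, NUMERIC)
        if kind not in (NUMERIC, CATEGORICAL):
            raise InvalidSpecError(f"unknown kind {kind!r} for column {col!r}")
        values = df[col]
        if kind == CATEGORICAL:
            codes = np.searchsorted(np.unique(values.to_numpy()), values.to_numpy())
            columns.append(codes.astype(np.float64))
        else:
            try:
                columns.append(values.to_numpy(dtype=np.float64))
            except (TypeError, ValueError) as exc:
                raise MissingValueError(
                    f"column {col!r} declared numeric but not parseable: {exc}"
                ) from exc
        kinds.append(kind)
    features = np.column_stack(columns) if columns else np.empty((len(df), 0))
    return Dataset(features, labels, kinds, name=path.stem)


def save_tabular_csv(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV plus a sidecar ``<path>.schema`` of column kinds."""
    path = Path(path)
    names = [f"f{i}" for i in range(ds.n_features)]
    df = pd.DataFrame(ds.features, columns=names)
    df["label"] = ds.labels
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".schema")
    sidecar.write_text(
        "".join(f"{n}\t{k}\n" for n, k in zip(names, ds.column_kinds))
    )


def _read_schema(path: Path) -> dict[str, str]:
    out = {}
    for line in path.read_text().splitlines():
        if line.strip():
            name, kind = line.split("\t")
            out[name] = kind
    return out


def one_hot_encode(ds: Dataset) -> Dataset:
    """Expand categorical columns into one indicator column per category.

    Numeric columns pass through unchanged and an all-numeric dataset is
    returned as-is.  The transform is applied to the whole dataset before
    any cross-validation split; indicator columns are a fixed re-encoding of
    observed categories, not a fitted statistic.  A categorical column with a
    single observed category yields one constant indicator and a warning.
    """
    if all(k == NUMERIC for k in ds.column_kinds):
        return ds
    columns = []
    for j, kind in enumerate(ds.column_kinds):
        col = ds.features[:, j]
        if kind == NUMERIC:
            columns.append(col)
            continue
        cats = np.unique(col)
        if len(cats) == 1:
            warnings.warn(
                f"categorical column {j} has a single category; "
                "emitting one constant indicator",
                stacklevel=2,
            )
        for cat in cats:
            columns.append((col == cat).astype(np.float64))
    features = np.column_stack(columns)
    return Dataset(features, ds.labels.copy(), [NUMERIC] * features.shape[1],
                   name=ds.name, seed=ds.seed)


def minority_class(labels: np.ndarray):
    """Return the class with the smaller count; ties go to the sorted-first class.

    The minority class of the full dataset is used as the positive class
    throughout the evaluation, which keeps asymmetric metrics comparable
    across datasets.  For exactly balanced data the sorted-first class is a
    deterministic, metric-symmetric choice.
    """
    classes, counts = np.unique(np.asarray(labels), return_counts=True)
    if len(classes) != 2:
        raise LabelArityError(f"expected two classes, got {len(classes)}")
    return classes[int(np.argmin(counts))]


def permute_labels(ds: Dataset, seed: int) -> Dataset:
    """Return a copy of ``ds`` with uniformly permuted labels.

    Permutation acts on the whole dataset before any split, breaking the
    feature-label link while preserving the label multiset (and therefore
    class counts, the minority class, and stratification feasibility).
    Features are shared with the input, not copied.
    """
    rng = np.random.default_rng(seed)
    labels = rng.permutation(ds.labels)
    return Dataset(ds.features, labels, list(ds.column_kinds),
                   name=f"{ds.name}/permuted-{seed}", seed=ds.seed)
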