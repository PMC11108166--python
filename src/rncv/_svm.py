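"""Low-overhead binary SVM built on scikit-learn's libsvm binding.

Nested cross-validation on datasets of a few dozen rows performs millions of
SVM fits whose individual training sets are tiny; at that scale the
estimator-level input validation of :class:`sklearn.svm.SVC` costs an order
of magnitude more than the libsvm solve itself.  This module calls the same
compiled libsvm routines that ``SVC`` uses, on pre-validated dense float64
arrays, and is asserted in the test suite to agree exactly with ``SVC``
(identical predictions and decision values) across kernels and parameters.

Inputs are class codes 0/1 (sorted class order is managed by the pipeline
layer); the decision function is oriented so that larger values favour class
code 1, matching ``SVC.decision_function``.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import _libsvm as libsvm

libsvm.set_verbosity_wrap(0)

_EMPTY = np.empty(0, dtype=np.float64)
_UNIT_CLASS_WEIGHT = np.ones(2, dtype=np.float64)

KERNELS = ("linear", "rbf", "poly", "sigmoid")


def resolve_gamma(gamma, X: np.ndarray) -> float:
    """Resolve ``'scale'``/``'auto'`` to a number for the data reaching the kernel.

    ``scale`` is ``1 / (n_features * var(X))`` (1.0 for zero variance) and
    ``auto`` is ``1 / n_features`` — the libsvm conventions.  Because the
    pipeline standardises before the SVM, ``scale`` sees the
    post-standardisation variance.
    """
    if isinstance(gamma, str):
        if gamma == "scale":
            var = float(X.var())
            return 1.0 / (X.shape[1] * var) if var != 0.0 else 1.0
        if gamma == "auto":
            return 1.0 / X.shape[1]
        raise ValueError(f"unknown gamma {gamma!r}")
    g = float(gamma)
    if g <= 0:
        raise ValueError(f"gamma must be positive, got {g}")
    return g


class SVMModel:
    """A fitted C-SVC over dense float64 data with class codes 0/1."""

    __slots__ = ("_model", "kernel", "gamma", "degree", "coef0")

    def __init__(self, model, kernel: str, gamma: float, degree: int, coef0: float):
        self._model = model
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class codes (0/1) for each row of ``X``."""
        codes = libsvm.predict(
            X, *self._model,
            svm_type=0, kernel=self.kernel, degree=self.degree,
            coef0=self.coef0, gamma=self.gamma, cache_size=200,
        )
        return codes.astype(np.int64)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the separating surface; positive favours code 1."""
        dec = libsvm.decision_function(
            X, *self._model,
            svm_type=0, kernel=self.kernel, degree=self.degree,
            coef0=self.coef0, gamma=self.gamma, cache_size=200,
        )
        # libsvm's binary decision values are oriented toward the first
        # class; negate to match the sklearn convention (favour code 1).
        return -dec.ravel()


def fit_svm(
    X: np.ndarray,
    y_codes: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "scale",
    kernel: str = "rbf",
    degree: int = 3,
    coef0: float = 0.0,
) -> SVMModel:
    """Fit a C-SVC.  ``X`` must be C-contiguous float64, ``y_codes`` float64 0/1."""
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    g = resolve_gamma(gamma, X)
    out = libsvm.fit(
        X, y_codes,
        svm_type=0, sample_weight=_EMPTY, class_weight=_UNIT_CLASS_WEIGHT,
        kernel=kernel, C=float(C), nu=0.5, probability=False, degree=degree,
        shrinking=True, tol=1e-3, cache_size=200, coef0=coef0,
        gamma=g, epsilon=0.1, max_iter=-1, random_seed=0,
    )
    # (support, SV, n_support, dual_coef, intercept, probA, probB) feed predict.
    return SVMModel(out[:7], kernel, g, degree, coef0)
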