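"""Linear two-class soft-margin SVM: training, decision values, feature ranking.

The classifier solves the standard primal

    minimize  (1/2)||w||^2 + C * sum_i max(0, 1 - y_i (w.x_i + b))

via libsvm's SMO solver (the backend behind both scikit-learn's ``SVC`` and
R's ``e1071``), reached here through scikit-learn's low-level binding so that
the many thousands of small fits in the nested cross-validation loops do not
pay the estimator-object overhead.  The model is reduced to its hyperplane
``(w, b)``; feature relevance is ``|w_j|``, the quantity driving recursive
feature elimination.

No rescaling happens inside the classifier: the pipeline standardizes
features upstream, on the training fold only.

Conventions (deterministic, documented):
- class labels are mapped to {+1, -1}; the positive class wins ties, i.e. a
  decision value of exactly 0 predicts +1;
- feature ranking sorts ascending in ``|w_j|`` with ties broken by ascending
  feature index (stable sort).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
from sklearn.svm import _libsvm

from .errors import ValidationError

_libsvm.set_verbosity_wrap(0)

#: Default soft-margin cost; the default of the libsvm interfaces.
DEFAULT_COST = 1.0
#: Default SMO stopping tolerance (libsvm's own default).
DEFAULT_TOL = 1e-3


def _fit_wb(X: np.ndarray, y: np.ndarray, cost: float, tol: float) -> tuple[np.ndarray, float]:
    """Raw libsvm C-SVC fit returning the hyperplane oriented so that
    ``w.x + b > 0`` predicts class +1.

    ``X`` must be float64 C-contiguous and ``y`` a float64 vector of +/-1
    containing both classes; validation lives in :func:`train`.
    """
    support, sv, _, sv_coef, intercept, *_ = _libsvm.fit(
        X, y, svm_type=0, kernel="linear", C=cost, tol=tol,
    )
    # The bundled libsvm groups binary classes in sorted label order and
    # orients the raw decision toward the first (-1), so the hyperplane is
    # negated to make w.x + b > 0 predict +1 (the same binary sign flip
    # scikit-learn's SVC applies).
    w = -(sv_coef[0] @ sv)
    b = -float(intercept[0])
    return w, b


@dataclass
class LinearModel:
    """Hyperplane of a trained linear SVM.

    ``class_map`` maps the two original labels to +1 / -1; predictions are
    reported in the original label space.  ``decision(x) = w.x + b``.
    """

    w: np.ndarray
    b: float
    cost: float
    class_map: dict[Hashable, int] = field(
        default_factory=lambda: {1: 1, -1: -1}
    )

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.isfinite(self.w).all() or not np.isfinite(self.b):
            raise ValidationError("hyperplane coefficients must be finite")
        if len(self.class_map) != 2 or set(self.class_map.values()) != {1, -1}:
            raise ValidationError("class_map must map exactly two labels to +1/-1")

    @property
    def n_features(self) -> int:
        return self.w.shape[0]

    def label_of(self, sign: int):
        for label, s in self.class_map.items():
            if s == sign:
                return label
        raise KeyError(sign)

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "cost": self.cost,
            "class_map": {str(k): v for k, v in self.class_map.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def train(
    X: np.ndarray,
    y: Sequence,
    cost: float = DEFAULT_COST,
    tol: float = DEFAULT_TOL,
    positive_label: Hashable | None = None,
) -> LinearModel:
    """Train the linear soft-margin SVM.

    Parameters
    ----------
    X : (n, p) array
        Training features (already preprocessed; no internal rescaling).
    y : length-n sequence
        Two distinct labels.  Numeric +/-1 vectors are used as-is; otherwise
        ``positive_label`` (default: lexicographically first) selects the
        label mapped to +1.
    cost : float
        Soft-margin cost C > 0.
    tol : float
        SMO stopping tolerance.
    """
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("X must be 2-D with at least 2 rows")
    if not np.isfinite(X).all():
        raise ValidationError("X contains NaN or infinite values")
    if cost <= 0:
        raise ValidationError("cost must be positive")

    labels = list(dict.fromkeys(y))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 classes, got {len(labels)}")

    if set(labels) == {1, -1} or set(labels) == {1.0, -1.0}:
        class_map = {1: 1, -1: -1}
        ypm = np.asarray(y, dtype=float)
    else:
        if positive_label is None:
            positive_label = sorted(labels, key=str)[0]
        if positive_label not in labels:
            raise ValidationError(f"positive_label {positive_label!r} not in y")
        class_map = {lab: (1 if lab == positive_label else -1) for lab in labels}
        ypm = np.array([class_map[lab] for lab in y], dtype=float)

    if len(ypm) != X.shape[0]:
        raise ValidationError("X and y length mismatch")

    w, b = _fit_wb(X, ypm, cost=float(cost), tol=float(tol))
    return LinearModel(w=w, b=b, cost=float(cost), class_map=class_map)


def decision_values(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Signed distances (up to ||w||) from the hyperplane: ``X @ w + b``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"X has {X.shape[1]} features but model has {model.n_features}"
        )
    return X @ model.w + model.b


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels; a decision value of exactly 0 maps to the positive class."""
    d = decision_values(model, X)
    pos, neg = model.label_of(1), model.label_of(-1)
    return np.where(d >= 0, pos, neg)


def rank_features(model: LinearModel) -> np.ndarray:
    """Feature indices ordered least-relevant first (ascending ``|w_j|``).

    Ties break by ascending feature index, so the ordering is a deterministic
    permutation of ``0..p-1``.
    """
    return np.argsort(np.abs(model.w), kind="stable")
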