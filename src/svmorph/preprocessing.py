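"""Training-fold covariate removal and standardization.

Both transforms are fitted on the training fold only and then applied
unchanged to held-out subjects — the held-out subject never influences the
regression coefficients or the scaling parameters, which is what keeps the
outer cross-validation estimate honest.

Covariate removal regresses each regional volume on an intercept, age and a
0/1 sex indicator by ordinary least squares and replaces the volume by the
residual; standardization then maps each residualized feature to mean zero
and unit sample variance (n-1 denominator).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: A training feature whose standard deviation falls below this is treated as
#: constant: it is mapped to zero instead of being divided by ~0.
DEGENERATE_SD_TOL = 1e-12


def _design(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    return np.column_stack([np.ones_like(age), age, sex])


@dataclass
class CovariateModel:
    """Per-feature OLS coefficients (intercept, beta_age, beta_sex)."""

    coef: np.ndarray  # shape (3, p)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.ndim != 2 or self.coef.shape[0] != 3:
            raise ValidationError(f"coef must have shape (3, p), got {self.coef.shape}")
        if not np.isfinite(self.coef).all():
            raise ValidationError("covariate coefficients must be finite")

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]

    def to_dict(self) -> dict:
        return {"coef": self.coef.tolist()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


@dataclass
class Scaler:
    """Per-feature mean / sample standard deviation, with a degeneracy flag.

    Features flagged degenerate (sd below :data:`DEGENERATE_SD_TOL` on the
    training fold) are mapped to zero rather than dropped, so feature
    indexing stays stable across folds.
    """

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray  # boolean mask

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (self.mean.shape == self.sd.shape == self.degenerate.shape):
            raise ValidationError("scaler fields must share one shape")
        if (self.sd < 0).any():
            raise ValidationError("standard deviations must be non-negative")

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "degenerate": self.degenerate.tolist(),
        }


def fit_covariate_model(X: np.ndarray, age: np.ndarray, sex: np.ndarray) -> CovariateModel:
    """OLS of every feature on [1, age, sex] over the training fold.

    Rank-deficient designs (constant age and sex, or n below the number of
    regressors) fall back to the minimum-norm least-squares solution via the
    pseudoinverse, with a logged warning; the betas then absorb into the
    intercept and residualization degrades gracefully to centering.
    """
    X = np.asarray(X, dtype=float)
    D = _design(age, sex)
    if X.shape[0] != D.shape[0]:
        raise ValidationError(f"X has {X.shape[0]} rows but covariates have {D.shape[0]}")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        logger.warning(
            "covariate design is rank deficient (rank %d < 3); "
            "using minimum-norm solution", rank,
        )
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    return CovariateModel(coef=coef)


def residualize(
    model: CovariateModel, X: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Subtract the model's predictions; never refits on the input."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"X has {X.shape[1]} features but model was fitted on {model.n_features}"
        )
    return X - _design(age, sex) @ model.coef


def fit_scaler(X: np.ndarray) -> Scaler:
    """Per-feature mean and sample (n-1) standard deviation of the training fold."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training subjects to fit a scaler")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return Scaler(mean=mean, sd=sd, degenerate=sd < DEGENERATE_SD_TOL)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != scaler.n_features:
        raise ValidationError(
            f"X has {X.shape[1]} features but scaler was fitted on {scaler.n_features}"
        )
    safe_sd = np.where(scaler.degenerate, 1.0, scaler.sd)
    Z = (X - scaler.mean) / safe_sd
    Z[:, scaler.degenerate] = 0.0
    return Z
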