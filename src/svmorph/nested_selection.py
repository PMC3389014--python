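"""Nested leave-one-subject-out SVM feature elimination.

The procedure estimates classification accuracy with an outer (first-level)
leave-one-subject-out loop, while the number of features to keep, Q, is
chosen inside each outer training fold by an inner (second-level)
leave-one-subject-out loop.  The held-out subject therefore contributes
nothing to covariate correction, scaling, feature ranking or Q — the design
that protects the accuracy estimate from double dipping.

Outer fold, for each held-out subject:

1. fit the covariate model (age, sex) and the scaler on the n-1 training
   subjects; residualize and standardize the training fold;
2. run the inner loop on the normalized training fold to pick Q;
3. train the SVM on all features, rank features by ``|w|``, keep the Q most
   discriminant, retrain on that subset;
4. transform the held-out subject with the training-fold transforms and
   predict.

Inner loop, for each inner-held-out subject of the normalized training fold:
train on all features once, compute ONE ranking from that model, then remove
the least relevant feature at a time per that fixed ranking, retraining and
predicting the inner subject at every feature count from p-1 down to 1.  The
count maximizing the pooled inner accuracy (smallest count on ties) is Q.

``rerank=True`` switches both loops to classic recursive feature
elimination, recomputing the ranking from the freshly retrained model after
every removal.  The fixed-ranking schedule is the default.

The whole procedure is deterministic: identical inputs give bitwise
identical predictions, Q values and feature sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .freesurfer_io import FeatureTable
from .preprocessing import (
    apply_scaler,
    fit_covariate_model,
    fit_scaler,
    residualize,
)
from .svm_core import DEFAULT_COST, DEFAULT_TOL, _fit_wb

logger = logging.getLogger(__name__)


@dataclass
class InnerCurve:
    """Pooled inner leave-one-out accuracy as a function of feature count."""

    feature_counts: list[int]  # descending
    accuracy_at_count: dict[int, float]
    chosen_q: int
    n_valid_folds: int

    def __post_init__(self) -> None:
        accs = self.accuracy_at_count
        if any(not (0.0 <= a <= 1.0) for a in accs.values()):
            raise ValidationError("accuracies must lie in [0, 1]")
        best = max(accs.values())
        if accs[self.chosen_q] != best or any(
            k < self.chosen_q for k, a in accs.items() if a == best
        ):
            raise ValidationError("chosen_q must be the smallest maximizing count")


@dataclass
class OuterFoldResult:
    """One outer fold: held-out subject, its Q, features kept, prediction."""

    held_out_subject: str
    q_used: int
    selected_features: list[str]  # most discriminant first
    predicted_label: str
    true_label: str
    decision_value: float
    #: relevance position per region from the fold's full-feature model
    #: (0 = most discriminant); used to order the consensus set.
    relevance_rank: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label

    def to_dict(self) -> dict:
        return {
            "held_out_subject": self.held_out_subject,
            "q_used": self.q_used,
            "selected_features": list(self.selected_features),
            "predicted_label": self.predicted_label,
            "true_label": self.true_label,
            "decision_value": self.decision_value,
        }


@dataclass
class OuterResult:
    """All outer folds plus the context needed for reporting."""

    folds: list[OuterFoldResult]
    region_names: list[str]
    positive_label: str

    @property
    def n_total(self) -> int:
        return len(self.folds)

    @property
    def n_correct(self) -> int:
        return sum(f.correct for f in self.folds)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    @property
    def per_fold_q(self) -> list[int]:
        return [f.q_used for f in self.folds]

    @property
    def decision_values(self) -> np.ndarray:
        return np.array([f.decision_value for f in self.folds])

    @property
    def true_labels(self) -> list[str]:
        return [f.true_label for f in self.folds]

    def selection_frequency(self) -> dict[str, float]:
        """Fraction of outer folds in which each region was selected."""
        counts = dict.fromkeys(self.region_names, 0)
        for f in self.folds:
            for name in f.selected_features:
                counts[name] += 1
        n = len(self.folds)
        return {name: c / n for name, c in counts.items()}

    def to_dict(self) -> dict:
        return {
            "positive_label": self.positive_label,
            "region_names": list(self.region_names),
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "folds": [f.to_dict() for f in self.folds],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _rank_asc(w: np.ndarray) -> np.ndarray:
    """Feature positions ordered least relevant first; index tie-break."""
    return np.argsort(np.abs(w), kind="stable")


def _eliminate_and_predict(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    x_test: np.ndarray,
    counts: Sequence[int],
    cost: float,
    tol: float,
    rerank: bool,
) -> dict[int, int]:
    """Predict ``x_test`` (+1/-1) at each feature count of the elimination path.

    The full-feature model is trained once; under the fixed-rank schedule its
    ranking alone decides every removal, under ``rerank`` the ranking is
    recomputed from each retrained model.
    """
    p = Xtr.shape[1]
    w, _ = _fit_wb(Xtr, ytr, cost, tol)
    preds: dict[int, int] = {}
    if rerank:
        keep = np.arange(p)
        w_cur = w
        for k in counts:
            drop = _rank_asc(w_cur)[0]
            keep = np.delete(keep, drop)
            w_cur, b_cur = _fit_wb(np.ascontiguousarray(Xtr[:, keep]), ytr, cost, tol)
            preds[k] = 1 if x_test[keep] @ w_cur + b_cur >= 0 else -1
    else:
        order = _rank_asc(w)
        for k in counts:
            keep = np.sort(order[p - k:])
            wk, bk = _fit_wb(np.ascontiguousarray(Xtr[:, keep]), ytr, cost, tol)
            preds[k] = 1 if x_test[keep] @ wk + bk >= 0 else -1
    return preds


def inner_accuracy_curve(
    X: np.ndarray,
    y: np.ndarray,
    cost: float = DEFAULT_COST,
    rerank: bool = False,
    tol: float = DEFAULT_TOL,
) -> InnerCurve:
    """Second-level leave-one-out accuracy at every feature count.

    ``X`` must already be covariate-corrected and normalized (the transforms
    are fitted once on the whole outer-training fold, upstream of this loop).
    Accuracy at each count pools correct predictions over all inner folds.
    An inner fold whose training subset loses a class entirely is excluded
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValidationError("need at least 2 features for an elimination curve")
    counts = list(range(p - 1, 0, -1))
    correct = dict.fromkeys(counts, 0)
    n_valid = 0
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        ytr = y[idx]
        if len(np.unique(ytr)) < 2:
            logger.warning(
                "inner fold %d skipped: training subset lost a class", i
            )
            continue
        n_valid += 1
        preds = _eliminate_and_predict(
            np.ascontiguousarray(X[idx]), ytr, X[i], counts, cost, tol, rerank
        )
        for k, pred in preds.items():
            if pred == y[i]:
                correct[k] += 1
    if n_valid == 0:
        raise ValidationError("no valid inner folds (every fold lost a class)")
    acc = {k: correct[k] / n_valid for k in counts}
    best = max(acc.values())
    chosen_q = min(k for k, a in acc.items() if a == best)
    return InnerCurve(
        feature_counts=counts,
        accuracy_at_count=acc,
        chosen_q=chosen_q,
        n_valid_folds=n_valid,
    )


def _select_features(
    Z: np.ndarray,
    ytr: np.ndarray,
    q: int,
    cost: float,
    tol: float,
    rerank: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the q most discriminant features (descending relevance)
    plus the relevance ordering of the full-feature model."""
    p = Z.shape[1]
    w_full, _ = _fit_wb(Z, ytr, cost, tol)
    full_desc = _rank_asc(w_full)[::-1]
    if not rerank or q == p:
        return full_desc[:q].copy(), full_desc
    keep = np.arange(p)
    w_cur = w_full
    while keep.size > q:
        drop = _rank_asc(w_cur)[0]
        keep = np.delete(keep, drop)
        w_cur, _ = _fit_wb(np.ascontiguousarray(Z[:, keep]), ytr, cost, tol)
    sel_desc = keep[_rank_asc(w_cur)[::-1]]
    return sel_desc, full_desc


def run_outer_loocv(
    table: FeatureTable,
    cost: float = DEFAULT_COST,
    rerank: bool = False,
    correct_covariates: bool = True,
    tol: float = DEFAULT_TOL,
) -> OuterResult:
    """First-level leave-one-subject-out accuracy with nested feature selection.

    Parameters
    ----------
    table : FeatureTable
        Volumes plus demographics; needs at least two subjects per class.
    cost : float
        SVM soft-margin cost C.
    rerank : bool
        Recompute the feature ranking after every elimination (classic RFE)
        instead of the default single fixed ranking per fold.
    correct_covariates : bool
        Regress age and sex out of every feature on the training fold before
        standardizing.  Disabling this exists to demonstrate confound leakage
        and should stay on for real analyses.
    """
    counts = table.class_counts()
    if len(counts) != 2 or min(counts.values()) < 2:
        raise ValidationError(
            f"need exactly 2 classes with >=2 subjects each, got {counts}"
        )
    if table.n_regions < 2:
        raise ValidationError("need at least 2 regions")

    X, y = table.X, table.y
    n = table.n_subjects
    pos, neg = table.positive_label, None
    for g in table.group_labels:
        if g != pos:
            neg = g
            break

    folds: list[OuterFoldResult] = []
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Xtr, ytr = X[idx], y[idx]
        age_tr, sex_tr = table.age[idx], table.sex[idx]

        if correct_covariates:
            cov = fit_covariate_model(Xtr, age_tr, sex_tr)
            R = residualize(cov, Xtr, age_tr, sex_tr)
        else:
            cov = None
            R = Xtr
        scaler = fit_scaler(R)
        Z = np.ascontiguousarray(apply_scaler(scaler, R))

        curve = inner_accuracy_curve(Z, ytr, cost=cost, rerank=rerank, tol=tol)
        q = curve.chosen_q

        sel_desc, full_desc = _select_features(Z, ytr, q, cost, tol, rerank)
        sel_sorted = np.sort(sel_desc)
        w_fin, b_fin = _fit_wb(np.ascontiguousarray(Z[:, sel_sorted]), ytr, cost, tol)

        x_new = X[i][None, :]
        if cov is not None:
            x_new = residualize(cov, x_new, table.age[i:i + 1], table.sex[i:i + 1])
        z_new = apply_scaler(scaler, x_new)[0]
        d = float(z_new[sel_sorted] @ w_fin + b_fin)
        pred = pos if d >= 0 else neg

        fold = OuterFoldResult(
            held_out_subject=table.subject_ids[i],
            q_used=q,
            selected_features=[table.region_names[j] for j in sel_desc],
            predicted_label=pred,
            true_label=table.group_labels[i],
            decision_value=d,
            relevance_rank={
                table.region_names[j]: pos_idx
                for pos_idx, j in enumerate(full_desc)
            },
        )
        logger.info(
            "outer fold %s: Q=%d, selected=%s, predicted=%s (true %s)",
            fold.held_out_subject, q, fold.selected_features,
            pred, fold.true_label,
        )
        folds.append(fold)

    return OuterResult(
        folds=folds,
        region_names=list(table.region_names),
        positive_label=pos,
    )


def consensus_features(result: OuterResult) -> list[str]:
    """Regions selected in every outer fold, most discriminant first.

    The intersection of the per-fold selected sets, ordered by the mean
    relevance-rank position of each region across folds (position 0 = most
    discriminant in that fold's full-feature model); name breaks ties.  An
    empty intersection is a valid outcome, not an error.
    """
    if not result.folds:
        raise ValidationError("result has no folds")
    common = set(result.folds[0].selected_features)
    for f in result.folds[1:]:
        common &= set(f.selected_features)
    mean_rank = {
        name: float(np.mean([f.relevance_rank[name] for f in result.folds]))
        for name in common
    }
    return sorted(common, key=lambda name: (mean_rank[name], name))
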