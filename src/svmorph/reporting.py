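"""Accuracy, binomial significance, ROC curves and per-region summaries.

The significance of a leave-one-out accuracy is assessed against a binomial
null: under chance performance each of the n held-out predictions is an
independent Bernoulli(chance) success, so the p-value is the exact upper
tail P(X >= n_correct) for X ~ Binomial(n_total, chance), computed by direct
summation of binomial terms (no normal approximation).  The conventional
two-class chance level is 0.5; the majority-class proportion is available as
an alternative null via the ``chance`` argument.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ValidationError
from .freesurfer_io import FeatureTable
from .nested_selection import OuterResult, consensus_features


def accuracy_percent(n_correct: int, n_total: int) -> float:
    """Accuracy as a percentage, rounded to 2 decimals (e.g. 37/39 -> 94.87)."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValidationError("need 0 <= n_correct <= n_total")
    return round(100.0 * n_correct / n_total, 2)


def binomial_pvalue(n_correct: int, n_total: int, chance: float = 0.5) -> float:
    """Exact one-sided binomial tail P(X >= n_correct), X ~ Bin(n_total, chance)."""
    if not 0 < chance < 1:
        raise ValidationError("chance must lie strictly between 0 and 1")
    if not 0 <= n_correct <= n_total or n_total <= 0:
        raise ValidationError("need 0 <= n_correct <= n_total with n_total > 0")
    terms = [
        math.comb(n_total, k) * chance**k * (1.0 - chance) ** (n_total - k)
        for k in range(n_correct, n_total + 1)
    ]
    return min(1.0, math.fsum(terms))


def p_value_band(p: float) -> str:
    """Conventional reporting band for a p-value ('p<0.001', 'p<0.01', ...)."""
    for cut in (0.001, 0.01, 0.05):
        if p < cut:
            return f"p<{cut}"
    return f"p={p:.3f}"


@dataclass
class RocCurve:
    """Empirical ROC curve: (FPR, TPR) per distinct score threshold, plus AUC."""

    points: list[tuple[float, float]]
    auc: float

    def __post_init__(self) -> None:
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise ValidationError("ROC must start at (0,0) and end at (1,1)")
        fprs = [p[0] for p in self.points]
        tprs = [p[1] for p in self.points]
        if (np.diff(fprs) < 0).any() or (np.diff(tprs) < 0).any():
            raise ValidationError("ROC points must be monotone non-decreasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def roc_points(scores: Sequence[float], labels: Sequence[float]) -> RocCurve:
    """Empirical ROC by descending score threshold; ties grouped; AUC by trapezoid.

    ``labels`` are +/-1.  The AUC is invariant under strictly increasing
    transforms of the scores and equals the probability that a random
    positive scores above a random negative (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if set(np.unique(labels)) != {-1.0, 1.0}:
        raise ValidationError("labels must contain both classes (+1 and -1)")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    return RocCurve(points=points, auc=auc)


@dataclass
class ClassificationReport:
    """Headline numbers of one nested leave-one-out run."""

    accuracy: float
    n_correct: int
    n_total: int
    p_value: float
    chance_level: float
    consensus_regions: list[str]
    per_fold_q: list[int]
    selection_frequency: dict[str, float] = field(default_factory=dict)
    positive_label: str = ""

    @property
    def accuracy_pct(self) -> float:
        return accuracy_percent(self.n_correct, self.n_total)

    @property
    def p_band(self) -> str:
        return p_value_band(self.p_value)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_percent": self.accuracy_pct,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "p_value": self.p_value,
            "p_band": self.p_band,
            "chance_level": self.chance_level,
            "consensus_regions": list(self.consensus_regions),
            "per_fold_q": list(self.per_fold_q),
            "selection_frequency": dict(self.selection_frequency),
            "positive_label": self.positive_label,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassificationReport":
        d = json.loads(Path(path).read_text())
        return cls(
            accuracy=d["accuracy"],
            n_correct=d["n_correct"],
            n_total=d["n_total"],
            p_value=d["p_value"],
            chance_level=d["chance_level"],
            consensus_regions=d["consensus_regions"],
            per_fold_q=d["per_fold_q"],
            selection_frequency=d["selection_frequency"],
            positive_label=d["positive_label"],
        )


def summarize(result: OuterResult, chance: float = 0.5) -> ClassificationReport:
    """Condense an :class:`OuterResult` into the report object."""
    return ClassificationReport(
        accuracy=result.accuracy,
        n_correct=result.n_correct,
        n_total=result.n_total,
        p_value=binomial_pvalue(result.n_correct, result.n_total, chance),
        chance_level=chance,
        consensus_regions=consensus_features(result),
        per_fold_q=result.per_fold_q,
        selection_frequency=result.selection_frequency(),
        positive_label=result.positive_label,
    )


def outer_roc(result: OuterResult) -> RocCurve:
    """ROC over the outer-fold decision values of the held-out subjects."""
    labels = np.where(
        np.asarray(result.true_labels) == result.positive_label, 1.0, -1.0
    )
    return roc_points(result.decision_values, labels)


def region_summary(
    table: FeatureTable,
    regions: Sequence[str],
) -> pd.DataFrame:
    """Five-number summary per region and group, plus the single-region AUC.

    Quartiles use linear interpolation.  The AUC scores subjects by the raw
    volume with the table's positive class as the positive label, so values
    below 0.5 mean the positive group has *smaller* volumes in that region.
    """
    unknown = [r for r in regions if r not in table.region_names]
    if unknown:
        raise ValidationError(f"unknown region(s) {unknown}")
    labels = table.y
    groups = sorted(set(table.group_labels))
    rows = []
    for r in regions:
        col = table.X[:, table.region_names.index(r)]
        auc = roc_points(col, labels).auc if len(groups) == 2 else float("nan")
        for g in groups:
            v = col[np.asarray(table.group_labels) == g]
            rows.append({
                "region": r,
                "group": g,
                "n": len(v),
                "min": float(v.min()),
                "q1": float(np.quantile(v, 0.25)),
                "median": float(np.median(v)),
                "q3": float(np.quantile(v, 0.75)),
                "max": float(v.max()),
                "auc": auc,
            })
    return pd.DataFrame(rows)


def plot_region_boxplots(
    table: FeatureTable,
    regions: Sequence[str],
    path: str | Path,
) -> None:
    """Per-region, per-group boxplots of the raw volumes (one panel per region)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(set(table.group_labels))
    glabels = np.asarray(table.group_labels)
    fig, axes = plt.subplots(
        1, len(regions), figsize=(3 * len(regions), 3.2), squeeze=False
    )
    for ax, r in zip(axes[0], regions):
        col = table.X[:, table.region_names.index(r)]
        ax.boxplot([col[glabels == g] for g in groups], tick_labels=groups)
        ax.set_title(r, fontsize=8)
        ax.set_ylabel("volume (mm³)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report_files(
    outdir: str | Path,
    result: OuterResult,
    table: FeatureTable,
    chance: float = 0.5,
    plots: bool = False,
) -> ClassificationReport:
    """Write report.json, roc.csv, region_summary.csv and selection_frequency.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = summarize(result, chance=chance)
    report.to_json(outdir / "report.json")
    outer_roc(result).to_dataframe().to_csv(outdir / "roc.csv", index=False)
    freq = pd.DataFrame(
        sorted(result.selection_frequency().items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["region", "selection_frequency"],
    )
    freq.to_csv(outdir / "selection_frequency.csv", index=False)
    regions = report.consensus_regions or list(table.region_names[: min(5, table.n_regions)])
    region_summary(table, regions).to_csv(outdir / "region_summary.csv", index=False)
    if plots:
        plot_region_boxplots(table, regions, outdir / "region_boxplots.png")
    return report
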