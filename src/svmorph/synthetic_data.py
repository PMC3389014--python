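"""Synthetic two-group volumetric cohorts with planted effects and confounds.

No public dataset accompanies the meditation-morphometry study design this
package implements, so every pipeline stage is exercised on synthetic
cohorts built to the same shape: two modest groups (19 meditators vs 20
non-meditators by default), ~121 regional volumes in cubic millimetres, a
handful of truly discriminative regions, and additive age and sex effects on
every region.

The generative model per subject i and region j is

    volume_ij = baseline_j
              + beta_age_j * age_i
              + beta_sex_j * sex_i
              + effect_size * noise_sd_j * group_i
              + eps_ij,        eps_ij ~ Normal(0, noise_sd_j^2)

with ``group_i`` a 0/1 indicator of the positive class, so ``effect_size``
is the standardized (in noise-sd units) mean group difference of a planted
region after the confounds are removed.  Ages are Gaussian per group
(truncated at 18 years); sex is Bernoulli.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .freesurfer_io import FeatureTable


def _default_planted(n_regions: int, n_planted: int = 5) -> list[int]:
    """Up to n_planted region indices spread evenly across the feature range."""
    k = min(n_planted, n_regions)
    return sorted(set(np.linspace(0, n_regions - 1, k).round().astype(int).tolist()))


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the emulated study cohort.

    ``beta_age_fraction`` and ``beta_sex_fraction`` express the confound
    slopes as fractions of each region's baseline volume: the default age
    slope of -0.2% per year reflects mild global atrophy with ageing, and
    the sex offset of +1% reflects slightly larger male volumes.
    """

    n_group_pos: int = 19
    n_group_neg: int = 20
    n_regions: int = 121
    planted_regions: list[int] | None = None
    effect_size: float = 2.0
    baseline_min: float = 500.0
    baseline_max: float = 20000.0
    noise_sd_fraction: float = 0.08
    age_mean_pos: float = 45.47
    age_sd_pos: float = 9.47
    age_mean_neg: float = 43.80
    age_sd_neg: float = 9.35
    beta_age_fraction: float = -0.002
    beta_sex_fraction: float = 0.01
    sex_proportion: float = 0.45
    positive_label: str = "meditator"
    negative_label: str = "nonmeditator"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_pos < 2 or self.n_group_neg < 2:
            raise ValidationError("group sizes must be at least 2")
        if self.n_regions < 2:
            raise ValidationError("need at least 2 regions")
        if self.planted_regions is None:
            self.planted_regions = _default_planted(self.n_regions)
        bad = [j for j in self.planted_regions if not 0 <= j < self.n_regions]
        if bad:
            raise ValidationError(f"planted region indices out of range: {bad}")
        if len(set(self.planted_regions)) != len(self.planted_regions):
            raise ValidationError("planted region indices must be unique")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if self.noise_sd_fraction <= 0:
            raise ValidationError("noise_sd_fraction must be positive")
        if not 0 < self.baseline_min <= self.baseline_max:
            raise ValidationError("need 0 < baseline_min <= baseline_max")
        if not 0 <= self.sex_proportion <= 1:
            raise ValidationError("sex_proportion must lie in [0, 1]")

    @property
    def planted_region_names(self) -> list[str]:
        return [_region_name(j) for j in self.planted_regions]


def _region_name(j: int) -> str:
    return f"region_{j:03d}"


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 18.0) -> np.ndarray:
    """Normal draws redrawn until all lie above ``lower``."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise ValidationError("truncated-normal sampling failed to converge")


def generate_cohort(config: SyntheticConfig) -> FeatureTable:
    """Draw one synthetic cohort as a :class:`FeatureTable`.

    Positive-class subjects come first; region ``region_jjj`` is column j.
    Identical configs (including seed) produce bitwise identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n_pos, n_neg = config.n_group_pos, config.n_group_neg
    n = n_pos + n_neg
    p = config.n_regions

    baseline = np.exp(rng.uniform(
        np.log(config.baseline_min), np.log(config.baseline_max), p
    ))
    noise_sd = config.noise_sd_fraction * baseline
    beta_age = config.beta_age_fraction * baseline
    beta_sex = config.beta_sex_fraction * baseline

    group = np.r_[np.ones(n_pos), np.zeros(n_neg)]
    age = np.empty(n)
    age[:n_pos] = _truncated_normal(rng, config.age_mean_pos, config.age_sd_pos, n_pos)
    age[n_pos:] = _truncated_normal(rng, config.age_mean_neg, config.age_sd_neg, n_neg)
    sex = (rng.random(n) < config.sex_proportion).astype(float)

    effect = np.zeros(p)
    effect[np.asarray(config.planted_regions, dtype=int)] = config.effect_size

    eps = rng.normal(0.0, 1.0, (n, p)) * noise_sd
    X = (
        baseline
        + np.outer(age, beta_age)
        + np.outer(sex, beta_sex)
        + np.outer(group, effect * noise_sd)
        + eps
    )

    return FeatureTable(
        subject_ids=[f"sub-{i + 1:03d}" for i in range(n)],
        group_labels=(
            [config.positive_label] * n_pos + [config.negative_label] * n_neg
        ),
        age=age,
        sex=sex,
        region_names=[_region_name(j) for j in range(p)],
        X=X,
        positive_label=config.positive_label,
    )


def make_null_labels(table: FeatureTable, seed: int) -> FeatureTable:
    """Return a copy of ``table`` with uniformly permuted group labels.

    Class counts are preserved and the features untouched, so repeated runs
    on permuted tables calibrate the pipeline's behaviour under the null of
    no label-feature association.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_subjects)
    return FeatureTable(
        subject_ids=list(table.subject_ids),
        group_labels=[table.group_labels[i] for i in perm],
        age=table.age.copy(),
        sex=table.sex.copy(),
        region_names=list(table.region_names),
        X=table.X.copy(),
        positive_label=table.positive_label,
    )


def write_stats_fixtures(table: FeatureTable, outdir: str | Path) -> None:
    """Emit per-subject aseg-dialect stats files plus demographics.csv.

    The files use the flat ``<subject>_aseg.stats`` layout understood by
    :func:`svmorph.freesurfer_io.load_stats_directory`, so a synthetic cohort
    can exercise the parsing path end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(table.subject_ids):
        lines = [
            "# Title Segmentation Statistics",
            f"# subjectname {sid}",
            "# ColHeaders  Index SegId NVoxels Volume_mm3 StructName",
        ]
        for j, region in enumerate(table.region_names):
            vol = float(table.X[i, j])
            lines.append(f"{j + 1:3d} {j + 1:4d} {int(round(vol)):8d} {vol!r:>12} {region}")
        (outdir / f"{sid}_aseg.stats").write_text("\n".join(lines) + "\n")
    pd.DataFrame({
        "subject_id": table.subject_ids,
        "group": table.group_labels,
        "age": table.age,
        "sex": table.sex,
    }).to_csv(outdir / "demographics.csv", index=False)
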