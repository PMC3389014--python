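"""Readers for FreeSurfer volumetric stats outputs and the subject x region feature table.

FreeSurfer's ``recon-all`` writes per-subject summary tables: ``aseg.stats``
for subcortical segmentations and ``lh.aparc.stats`` / ``rh.aparc.stats`` for
the cortical parcellation of each hemisphere.  Both are plain-text files in
which lines beginning with ``#`` carry metadata (including a ``ColHeaders``
line naming the data columns) and the remaining lines are whitespace-delimited
rows, one per anatomical structure.  This module parses the per-structure
volume column of either dialect (``Volume_mm3`` for aseg, ``GrayVol`` for
aparc) and assembles the volumes of many subjects into a single
:class:`FeatureTable`, the pipeline's central container.

Whole-brain summary measures (intracranial volume, total gray, ...) live in
``# Measure`` comment lines, not data rows, so they are naturally excluded
from the assembled region set.

Note on naming: FreeSurfer's segmentation labels the basal putamen
``vessel`` (it is an area with prominent vascular space); the label is kept
verbatim here.  Cortical (aparc) structures are prefixed ``lh_`` / ``rh_`` so
bilateral structures stay distinct regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import StatsFormatError, StatsParseError, ValidationError

logger = logging.getLogger(__name__)

#: Column holding the structure volume, per dialect.
_VOLUME_COLUMN = {"aseg": "Volume_mm3", "aparc": "GrayVol"}
_NAME_COLUMN = "StructName"

_DEMOGRAPHIC_COLUMNS = ("subject_id", "group", "age", "sex")

_SEX_CODES = {
    "0": 0, "1": 1,
    "f": 0, "m": 1,
    "female": 0, "male": 1,
}


@dataclass
class RegionVolumeRecord:
    """Per-structure volumes parsed from one stats file of one subject.

    ``volumes`` preserves the file's row order and maps the verbatim
    structure label to its volume in cubic millimetres.
    """

    subject_id: str
    source_file: str
    volumes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vol in self.volumes.items():
            if not np.isfinite(vol) or vol < 0:
                raise ValidationError(
                    f"{self.source_file}: volume of {name!r} is {vol!r} "
                    "(must be finite and non-negative)"
                )


@dataclass
class FeatureTable:
    """Subjects x regions volume matrix joined with demographics.

    Attributes
    ----------
    subject_ids : list of str
        One id per row of ``X``.
    group_labels : list of str
        Raw group label per subject (e.g. ``"meditator"`` / ``"control"``).
    age : ndarray, shape (n,)
        Age in years.
    sex : ndarray, shape (n,)
        0/1 indicator (1 = male under the default encoding).
    region_names : list of str
        Column names of ``X``; order is identical for every subject.
    X : ndarray, shape (n, p)
        Regional volumes in cubic millimetres.
    positive_label : str
        The group label mapped to class +1 by the classifier.  Defaults to
        the lexicographically first distinct label, which keeps the mapping
        deterministic when the caller does not care about orientation.
    """

    subject_ids: list[str]
    group_labels: list[str]
    age: np.ndarray
    sex: np.ndarray
    region_names: list[str]
    X: np.ndarray
    positive_label: str | None = None

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.subject_ids)
        if self.X.shape != (n, len(self.region_names)):
            raise ValidationError(
                f"X has shape {self.X.shape}, expected "
                f"({n}, {len(self.region_names)})"
            )
        if len(self.group_labels) != n or self.age.shape != (n,) or self.sex.shape != (n,):
            raise ValidationError("demographic vectors must have one entry per subject")
        if not np.isfinite(self.X).all():
            raise ValidationError("feature matrix contains missing or non-finite cells")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValidationError("duplicate region names")
        labels = sorted(set(self.group_labels))
        if self.positive_label is None:
            self.positive_label = labels[0]
        elif self.positive_label not in labels:
            raise ValidationError(
                f"positive_label {self.positive_label!r} not among group labels {labels}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def y(self) -> np.ndarray:
        """Class labels as +/-1 (+1 for ``positive_label``)."""
        return np.where(np.asarray(self.group_labels) == self.positive_label, 1.0, -1.0)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.group_labels:
            counts[g] = counts.get(g, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.region_names)
        df.insert(0, "sex", self.sex)
        df.insert(0, "age", self.age)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the tidy CSV interchange format (one row per subject).

        Floats are written with 17 significant digits so a read-back
        reproduces the matrix bit for bit.
        """
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, positive_label: str | None = None) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _DEMOGRAPHIC_COLUMNS if c not in df.columns]
        if missing:
            raise StatsFormatError(f"{path}: missing columns {missing}")
        regions = [c for c in df.columns if c not in _DEMOGRAPHIC_COLUMNS]
        if not regions:
            raise StatsFormatError(f"{path}: no region columns")
        return cls(
            subject_ids=[str(s) for s in df["subject_id"]],
            group_labels=[str(g) for g in df["group"]],
            age=df["age"].to_numpy(dtype=float),
            sex=df["sex"].to_numpy(dtype=float),
            region_names=regions,
            X=df[regions].to_numpy(dtype=float),
            positive_label=positive_label,
        )


def _find_colheaders(lines: Iterable[tuple[int, str]], path: Path) -> list[str]:
    for _, line in lines:
        if line.startswith("#") and "ColHeaders" in line:
            toks = line.lstrip("#").split()
            return toks[toks.index("ColHeaders") + 1 :]
    raise StatsFormatError(f"{path}: no '# ColHeaders' line found")


def parse_stats_file(
    path: str | Path,
    dialect: str,
    subject_id: str | None = None,
) -> RegionVolumeRecord:
    """Parse one FreeSurfer stats file into a :class:`RegionVolumeRecord`.

    Parameters
    ----------
    path : path
        The ``aseg.stats`` or ``?h.aparc.stats`` file.
    dialect : {"aseg", "aparc"}
        Selects the volume column (``Volume_mm3`` vs ``GrayVol``).  For the
        aparc dialect the hemisphere is read from the ``# hemi`` header line
        and region names are prefixed ``lh_`` / ``rh_``.
    subject_id : str, optional
        Overrides the id found in the ``# subjectname`` header; falls back to
        the file stem when neither is available.

    Raises
    ------
    StatsFormatError
        Missing volume column, missing column headers, or (aparc) missing
        hemisphere declaration.
    StatsParseError
        A data row whose volume field is not numeric (the message cites the
        line number).
    ValidationError
        Duplicate structure label within the file.
    """
    path = Path(path)
    if dialect not in _VOLUME_COLUMN:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'aseg' or 'aparc'")
    volume_col = _VOLUME_COLUMN[dialect]

    numbered = [(i + 1, raw.rstrip("\n")) for i, raw in enumerate(path.read_text().splitlines())]
    header_id: str | None = None
    hemi: str | None = None
    for _, line in numbered:
        if line.startswith("#"):
            toks = line.lstrip("#").split()
            if len(toks) >= 2 and toks[0] == "subjectname":
                header_id = toks[1]
            if len(toks) >= 2 and toks[0] == "hemi":
                hemi = toks[1]

    columns = _find_colheaders(numbered, path)
    if volume_col not in columns or _NAME_COLUMN not in columns:
        raise StatsFormatError(
            f"{path}: required columns {_NAME_COLUMN!r} and {volume_col!r} "
            f"not in ColHeaders {columns}"
        )
    vol_idx = columns.index(volume_col)
    name_idx = columns.index(_NAME_COLUMN)

    prefix = ""
    if dialect == "aparc":
        if hemi not in ("lh", "rh"):
            raise StatsFormatError(
                f"{path}: aparc dialect requires a '# hemi lh|rh' header line "
                "to keep bilateral structures distinct"
            )
        prefix = hemi + "_"

    volumes: dict[str, float] = {}
    for lineno, line in numbered:
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) <= max(vol_idx, name_idx):
            raise StatsParseError(
                f"{path}:{lineno}: row has {len(toks)} fields, "
                f"expected at least {max(vol_idx, name_idx) + 1}"
            )
        name = prefix + toks[name_idx]
        try:
            vol = float(toks[vol_idx])
        except ValueError:
            raise StatsParseError(
                f"{path}:{lineno}: volume field {toks[vol_idx]!r} is not numeric"
            ) from None
        if name in volumes:
            raise ValidationError(f"{path}: duplicate region label {name!r}")
        volumes[name] = vol

    sid = subject_id or header_id or path.stem
    return RegionVolumeRecord(subject_id=sid, source_file=str(path), volumes=volumes)


def _coerce_sex(value: object) -> float:
    key = str(value).strip().lower()
    if key in _SEX_CODES:
        return float(_SEX_CODES[key])
    try:
        return float(key)
    except ValueError:
        raise ValidationError(f"unrecognised sex code {value!r}") from None


def assemble_feature_table(
    records: Sequence[RegionVolumeRecord],
    demographics: pd.DataFrame,
    region_list: Sequence[str] | None = None,
    positive_label: str | None = None,
) -> FeatureTable:
    """Join per-subject volume records with demographics into a FeatureTable.

    Records belonging to the same subject (e.g. aseg plus both aparc
    hemispheres) are merged.  When ``region_list`` is omitted, the region set
    defaults to the lexicographically sorted intersection of regions present
    for every subject; otherwise the given order is kept.

    Subjects appearing in ``records`` but not in ``demographics`` are excluded
    with a logged warning.  A demographics subject missing a requested region
    (or missing from the records entirely) is a :class:`ValidationError`.
    """
    demographics = pd.DataFrame(demographics)
    missing = [c for c in _DEMOGRAPHIC_COLUMNS if c not in demographics.columns]
    if missing:
        raise ValidationError(f"demographics table missing columns {missing}")

    by_subject: dict[str, dict[str, float]] = {}
    for rec in records:
        merged = by_subject.setdefault(rec.subject_id, {})
        for name, vol in rec.volumes.items():
            if name in merged and merged[name] != vol:
                raise ValidationError(
                    f"subject {rec.subject_id!r}: conflicting volumes for region {name!r}"
                )
            merged[name] = vol

    wanted = [str(s) for s in demographics["subject_id"]]
    extra = sorted(set(by_subject) - set(wanted))
    if extra:
        logger.warning(
            "excluding %d subject(s) present in records but not demographics: %s",
            len(extra), ", ".join(extra),
        )

    absent = [s for s in wanted if s not in by_subject]
    if absent:
        raise ValidationError(f"no volume records for demographics subject(s) {absent}")

    if region_list is None:
        common: set[str] | None = None
        for sid in wanted:
            names = set(by_subject[sid])
            common = names if common is None else common & names
        regions = sorted(common or ())
    else:
        regions = list(region_list)
        for sid in wanted:
            gaps = [r for r in regions if r not in by_subject[sid]]
            if gaps:
                raise ValidationError(
                    f"subject {sid!r} is missing requested region(s) {gaps}"
                )
    if len(regions) < 1:
        raise ValidationError("empty region set after intersection")

    X = np.array([[by_subject[sid][r] for r in regions] for sid in wanted], dtype=float)
    return FeatureTable(
        subject_ids=wanted,
        group_labels=[str(g) for g in demographics["group"]],
        age=demographics["age"].to_numpy(dtype=float),
        sex=np.array([_coerce_sex(v) for v in demographics["sex"]]),
        region_names=regions,
        X=X,
        positive_label=positive_label,
    )


def load_stats_directory(
    stats_dir: str | Path,
    demographics: str | Path | pd.DataFrame,
    region_list: Sequence[str] | None = None,
    positive_label: str | None = None,
) -> FeatureTable:
    """Parse every recognised stats file under ``stats_dir`` and assemble.

    Expects per-subject files named ``<subject>_aseg.stats``,
    ``<subject>_lh.aparc.stats`` and/or ``<subject>_rh.aparc.stats`` (flat
    layout), or the standard FreeSurfer ``<subject>/stats/*.stats`` tree.
    """
    stats_dir = Path(stats_dir)
    if not isinstance(demographics, pd.DataFrame):
        demographics = pd.read_csv(demographics)

    records: list[RegionVolumeRecord] = []
    for f in sorted(stats_dir.rglob("*.stats")):
        name = f.name
        if "aparc" in name:
            dialect = "aparc"
        elif "aseg" in name:
            dialect = "aseg"
        else:
            continue
        sid = None
        if "_" in name:  # flat "<subject>_<kind>.stats" layout
            sid = name.split("_")[0]
        elif f.parent.name == "stats":  # FreeSurfer <subject>/stats/ tree
            sid = f.parent.parent.name
        records.append(parse_stats_file(f, dialect=dialect, subject_id=sid))
    if not records:
        raise ValidationError(f"no aseg/aparc stats files found under {stats_dir}")
    return assemble_feature_table(records, demographics, region_list, positive_label)
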