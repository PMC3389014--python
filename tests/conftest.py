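import numpy as np
import pytest

from svmorph import FeatureTable, SyntheticConfig, generate_cohort

ASEG_FIXTURE = """\
# Title Segmentation Statistics
# subjectname sub-01
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1484985.0, mm^3
# ColHeaders  Index SegId NVoxels Volume_mm3 StructName
  1   10  7500  7500.0  Left-Thalamus
  2   49  7600  7600.0  Right-Thalamus
  3   30    30    30.0  vessel
"""

APARC_FIXTURE = """\
# Table of FreeSurfer cortical parcellation anatomical statistics
# subjectname sub-01
# hemi lh
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd
entorhinal   610   420  1986.5  3.3  0.7  0.1  0.03  5  0.7
precentral  8210  5340 13550.0  2.5  0.5  0.1  0.02 60  5.8
"""


@pytest.fixture
def aseg_file(tmp_path):
    p = tmp_path / "sub-01_aseg.stats"
    p.write_text(ASEG_FIXTURE)
    return p


@pytest.fixture
def aparc_file(tmp_path):
    p = tmp_path / "sub-01_lh.aparc.stats"
    p.write_text(APARC_FIXTURE)
    return p


@pytest.fixture
def tiny_table():
    """8 subjects x 3 regions, feature 0 strongly discriminative."""
    rng = np.random.default_rng(42)
    n = 8
    groups = ["meditator"] * 4 + ["control"] * 4
    X = rng.normal(0.0, 1.0, (n, 3)) + 1000.0
    X[:4, 0] += 8.0
    return FeatureTable(
        subject_ids=[f"s{i}" for i in range(n)],
        group_labels=groups,
        age=rng.uniform(30, 60, n),
        sex=np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float),
        region_names=["rA", "rB", "rC"],
        X=X,
        positive_label="meditator",
    )


@pytest.fixture
def planted_cohort():
    """20+20 subjects, 12 regions, 3 planted at a strong effect (fast)."""
    cfg = SyntheticConfig(
        n_group_pos=20, n_group_neg=20, n_regions=12,
        planted_regions=[1, 5, 9], effect_size=2.0, seed=7,
    )
    return cfg, generate_cohort(cfg)
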