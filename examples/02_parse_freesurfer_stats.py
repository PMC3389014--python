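"""Parse FreeSurfer-style stats files into the pipeline's feature table.

Writes a tiny aseg-dialect and aparc-dialect file (the '#' header plus
whitespace-delimited rows format of FreeSurfer's recon-all), parses them,
and assembles a subject x region table joined with demographics.
"""

import tempfile
from pathlib import Path

import pandas as pd

from svmorph import assemble_feature_table, parse_stats_file

ASEG = """\
# Title Segmentation Statistics
# subjectname sub-01
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1484985.0, mm^3
# ColHeaders  Index SegId NVoxels Volume_mm3 StructName
  1   10  7500  7500.0  Left-Thalamus
  2   49  7600  7600.0  Right-Thalamus
  3   30    30    30.0  vessel
"""

APARC = """\
# Table of FreeSurfer cortical parcellation anatomical statistics
# subjectname sub-01
# hemi rh
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg
parsopercularis  2800  1900  4820.0  2.6
precentral       8210  5340 13550.0  2.5
"""

tmp = Path(tempfile.mkdtemp())
(tmp / "sub-01_aseg.stats").write_text(ASEG)
(tmp / "sub-01_rh.aparc.stats").write_text(APARC)

aseg = parse_stats_file(tmp / "sub-01_aseg.stats", dialect="aseg")
aparc = parse_stats_file(tmp / "sub-01_rh.aparc.stats", dialect="aparc")
print("aseg volumes :", aseg.volumes)
print("aparc volumes:", aparc.volumes)

# a second subject with the same regions, slightly different volumes
aseg2 = type(aseg)("sub-02", "mem", {k: v * 1.04 for k, v in aseg.volumes.items()})
aparc2 = type(aparc)("sub-02", "mem", {k: v * 0.97 for k, v in aparc.volumes.items()})

demo = pd.DataFrame({
    "subject_id": ["sub-01", "sub-02"],
    "group": ["meditator", "nonmeditator"],
    "age": [45.0, 43.0],
    "sex": ["F", "M"],
})
table = assemble_feature_table([aseg, aparc, aseg2, aparc2], demo)
print("\nassembled", table.n_subjects, "subjects x", table.n_regions, "regions:")
print(table.to_dataframe().to_string(index=False))
print()
print("Notes: summary '# Measure' lines (ICV etc.) are ignored; the FreeSurfer")
print("label 'vessel' (basal putamen) is kept verbatim; aparc regions get an")
print("lh_/rh_ prefix so bilateral structures stay distinct features.")
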