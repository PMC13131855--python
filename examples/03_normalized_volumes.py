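"""eTIV-normalized ventricle and choroid-plexus volumes.

Generates a synthetic segmentation-statistics table, writes and re-reads
it through the parser, and prints each subject's normalized volumes
(structure volume / estimated total intracranial volume).  Normalized
lateral-ventricle volumes around 0.01 are typical for healthy adults.
"""

import tempfile
from pathlib import Path

from csfmarkers import generate_volumetric_table, read_aseg_table, records_to_frame

table = generate_volumetric_table(n_subjects=5, seed=3)
path = Path(tempfile.mkdtemp()) / "volumes.tsv"
table.to_csv(path, sep="\t", index=False)

frame = records_to_frame(read_aseg_table(path))
print(frame.round(5).to_string())
print("\ncolumns are structure volume / eTIV (dimensionless)")
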