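"""Categorical encoding of a mammography-style table.

Builds a tiny CSV in the UCI mammographic-mass layout (BI-RADS assessment,
age, mass shape/margin/density, biopsy severity), encodes each subcategory
as an indicator/complement pair of binaries plus a rescaled age column, and
prints the resulting 27 feature names. Rows with missing values ('?') are
dropped.
"""

import io

from colabel import BIRADS_SCHEMA, read_table

csv = io.StringIO(
    "birads,age,shape,margin,density,severity\n"
    "5,67,3,5,3,1\n"
    "4,43,1,1,?,1\n"
    "5,58,4,5,3,1\n"
    "4,28,1,1,3,0\n"
)

dataset = read_table(csv, BIRADS_SCHEMA)
print(f"{dataset.n_rows} usable rows (one dropped for a missing density)")
print(f"{dataset.n_features} features; labels: {dataset.label_names}")
for name in dataset.feature_names:
    print(" ", name)
# shape (4) + margin (5) + density (4) subcategories, each as an
# indicator/complement pair -> 26 binaries, plus age rescaled to [0, 1].
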