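"""Infer KO abundances from a tiny OTU table.

Copy-number normalisation divides each OTU's counts by its 16S rRNA gene
copy number (approximating organism abundance); the KO prediction is the
product with the per-genome gene-content matrix, and every summand is kept
as an (OTU, KO, sample) contribution record.
"""

import pandas as pd

from komix import (
    FeatureTable,
    GeneContentMatrix,
    PathwayDB,
    collapse_to_pathways,
    normalize_by_copy_number,
    predict_metagenome,
)

otu = FeatureTable(
    values=pd.DataFrame(
        {"gut_1": [10.0, 4.0], "gut_2": [20.0, 8.0]},
        index=["OTU_1", "OTU_2"]),
    scale="counts",
)
gcm = GeneContentMatrix(
    content=pd.DataFrame(
        {"K00001": [3.0, 2.0], "K00002": [0.0, 1.0]},
        index=["OTU_1", "OTU_2"]),
    copy_number=pd.Series({"OTU_1": 2.0, "OTU_2": 1.0}),
)

norm = normalize_by_copy_number(otu, gcm)
print("copy-number normalised abundances:")
print(norm.values, "\n")          # OTU_1 halved (2 ribosomal copies)

ko_table, contributions = predict_metagenome(norm, gcm)
print("predicted KO abundances:")
print(ko_table.values, "\n")      # K00001 in gut_1 = 5*3 + 4*2 = 23
print("per-OTU contributions to K00001 in gut_1:")
print(contributions.records.query(
    "ko_id == 'K00001' and sample_id == 'gut_1'"), "\n")

db = PathwayDB(members={"path_demo": {"K00001", "K00002"}})
print("pathway-collapsed abundances (sum of member KOs):")
print(collapse_to_pathways(ko_table, db).values)
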