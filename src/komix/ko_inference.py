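"""16S-based metagenome inference: copy-number normalisation, KO prediction,
per-OTU contribution accounting, pathway collapse and genus aggregation.

The prediction is the bilinear core of PICRUSt-style inference: divide each
OTU's counts by its genome's 16S rRNA gene copy number (approximating organism
abundance), then multiply through the OTU x KO gene-content matrix to obtain
predicted KO abundances per sample.  Each summand of that product is kept as an
(OTU, KO, sample) contribution record, which later lets enriched pathways be
deconvoluted back into the taxa that drive them.

Predicted abundances are kept as reals; ``round_predictions=True`` reproduces
the legacy integer-rounding behaviour of early inference tools.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FeatureTable, GeneContentMatrix, PathwayDB, ValidationError

logger = logging.getLogger("komix.infer")

#: Relative tolerance at which contribution sums must reconstruct KO abundances.
CONSERVATION_RTOL = 1e-9


@dataclass
class ContributionTable:
    """Long-format (otu_id, ko_id, sample_id, contribution) records.

    Zero contributions are omitted; for every (ko, sample) the contributions
    over OTUs sum to the predicted KO abundance (relative tolerance 1e-9).
    """

    records: pd.DataFrame  # columns: otu_id, ko_id, sample_id, contribution

    def __post_init__(self) -> None:
        expected = ["otu_id", "ko_id", "sample_id", "contribution"]
        if list(self.records.columns) != expected:
            raise ValidationError(
                f"contribution table columns must be {expected}"
            )

    def for_kos(self, kos: set[str]) -> pd.DataFrame:
        return self.records[self.records.ko_id.isin(kos)]

    def __len__(self) -> int:
        return len(self.records)


def normalize_by_copy_number(
    otu_table: FeatureTable, gcm: GeneContentMatrix
) -> FeatureTable:
    """Divide each OTU's counts by its 16S rRNA gene copy number.

    The result approximates organism abundance and stays on the counts scale
    (fractional values allowed).
    """
    if otu_table.scale != "counts":
        raise ValidationError("copy-number normalisation expects scale=counts")
    missing = otu_table.values.index.difference(gcm.copy_number.index)
    if len(missing):
        raise ValidationError(
            f"OTUs without a 16S copy number: {list(missing)[:10]}"
        )
    cn = gcm.copy_number.reindex(otu_table.values.index)
    norm = otu_table.values.div(cn, axis=0)
    return FeatureTable(values=norm, scale="counts",
                        feature_meta=otu_table.feature_meta)


def predict_metagenome(
    norm_table: FeatureTable,
    gcm: GeneContentMatrix,
    round_predictions: bool = False,
) -> tuple[FeatureTable, ContributionTable]:
    """Predict KO abundances and keep the per-OTU summands.

    KO abundance(ko, sample) = sum over OTUs of
    normalised_abundance(otu, sample) * gene_content(otu, ko).
    All-zero KO rows are dropped (count logged).
    """
    missing = norm_table.values.index.difference(gcm.content.index)
    if len(missing):
        raise ValidationError(
            f"OTUs absent from gene-content matrix: {list(missing)[:10]}"
        )
    content = gcm.content.reindex(norm_table.values.index)
    abund = norm_table.values  # otus x samples
    ko_values = content.T.to_numpy() @ abund.to_numpy()  # kos x samples
    ko_table = pd.DataFrame(ko_values, index=content.columns,
                            columns=abund.columns)

    # contribution records from the nonzero (otu, ko) content cells
    c = content.to_numpy()
    a = abund.to_numpy()
    otu_idx, ko_idx = np.nonzero(c)
    otu_ids = np.asarray(content.index)
    ko_ids = np.asarray(content.columns)
    sample_ids = np.asarray(abund.columns)
    n_samp = len(sample_ids)
    contrib = c[otu_idx, ko_idx][:, None] * a[otu_idx, :]  # pairs x samples
    pair_keep, samp_keep = np.nonzero(contrib)
    records = pd.DataFrame(
        {
            "otu_id": otu_ids[otu_idx[pair_keep]],
            "ko_id": ko_ids[ko_idx[pair_keep]],
            "sample_id": sample_ids[samp_keep],
            "contribution": contrib[pair_keep, samp_keep],
        }
    )

    nonzero = (ko_table.to_numpy() != 0).any(axis=1)
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero predicted KO rows", n_dropped)
    ko_table = ko_table.loc[nonzero]
    if round_predictions:
        # legacy integer parity; contribution records keep the raw summands
        ko_table = ko_table.round(0)
    return (
        FeatureTable(values=ko_table, scale="counts"),
        ContributionTable(records=records),
    )


def collapse_to_pathways(ko_table: FeatureTable, db: PathwayDB) -> FeatureTable:
    """Sum member-KO abundances per pathway.

    A KO belonging to several pathways contributes its full abundance to each
    of them (abundance is duplicated across pathways, the convention of
    PICRUSt's categorize_by_function).  Pathways with no measured member KO
    are dropped with a log message.
    """
    measured = set(ko_table.values.index)
    rows = {}
    dropped = 0
    for pid in sorted(db.members):
        present = sorted(db.members[pid] & measured)
        if not present:
            dropped += 1
            continue
        rows[pid] = ko_table.values.loc[present].sum(axis=0)
    if dropped:
        logger.info("dropping %d pathways with no measured KOs", dropped)
    if not rows:
        raise ValidationError("no pathway has any measured member KO")
    values = pd.DataFrame(rows).T
    values.columns = ko_table.values.columns
    return FeatureTable(values=values, scale=ko_table.scale)


_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_genus(taxonomy: str) -> str:
    """Extract the genus from a Greengenes-style 7-rank taxonomy string.

    An empty ``g__`` field yields ``unclassified_<lowest named rank>``, e.g.
    ``g__`` under family ``f__S24-7`` becomes ``unclassified_S24-7``.
    """
    fields = {}
    for part in str(taxonomy).split(";"):
        part = part.strip()
        m = re.match(r"([kpcofgs]__)(.*)", part)
        if m:
            fields[m.group(1)] = m.group(2).strip()
    genus = fields.get("g__", "")
    if genus:
        return genus
    for prefix in ("f__", "o__", "c__", "p__", "k__"):
        name = fields.get(prefix, "")
        if name:
            return f"unclassified_{name}"
    return "unclassified_unknown"


def aggregate_to_genus(otu_table: FeatureTable) -> FeatureTable:
    """Sum OTU counts over the genus field of their taxonomy strings."""
    tax = otu_table.taxonomy()  # raises if absent
    genera = tax.map(parse_genus)
    values = otu_table.values.groupby(genera, sort=True).sum()
    values.index.name = None
    return FeatureTable(values=values, scale=otu_table.scale)


def check_conservation(
    ko_table: FeatureTable, contributions: ContributionTable
) -> float:
    """Max relative gap between contribution sums and predicted abundances."""
    sums = (
        contributions.records.groupby(["ko_id", "sample_id"], sort=False)[
            "contribution"
        ]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(index=ko_table.values.index, columns=ko_table.values.columns,
                 fill_value=0.0)
    )
    denom = np.maximum(np.abs(ko_table.values.to_numpy()), 1.0)
    gap = np.abs(sums.to_numpy() - ko_table.values.to_numpy()) / denom
    return float(gap.max()) if gap.size else 0.0
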