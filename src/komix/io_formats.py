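"""Readers, writers and in-memory containers for every table the pipeline touches.

All files are tab-delimited UTF-8 text; lines starting with ``#`` are comments
(the legacy QIIME/PICRUSt table dialect).  Feature tables have features as rows
and samples as columns, with the feature id in the first column; an optional
``taxonomy`` column is moved into per-feature metadata on read.

The containers here (:class:`FeatureTable`, :class:`GeneContentMatrix`,
:class:`PathwayDB`, :class:`GeneKoMap`, :class:`Design`) validate their
invariants on construction, so downstream modules can assume clean input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("komix.io")

#: Column name recognised as taxonomy metadata in feature-table files.
TAXONOMY_COLUMN = "taxonomy"

_VALID_SCALES = ("counts", "log2")


class ValidationError(ValueError):
    """Raised when an input table violates a declared invariant."""


def _find_duplicates(items) -> list:
    seen: set = set()
    dups: list = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class FeatureTable:
    """A features x samples abundance matrix with per-feature metadata.

    Serves three roles: OTU count tables, inferred KO tables and host
    expression matrices.  ``scale`` declares whether cells are raw
    (possibly fractional) counts or log2-scale intensities.

    Parameters
    ----------
    values
        DataFrame, features as rows (index = feature ids), samples as
        columns.  No missing cells; absences are explicit zeros.
    feature_meta
        Per-feature key -> string metadata, e.g. a Greengenes taxonomy
        string under the key ``taxonomy``.
    scale
        ``"counts"`` (values must be >= 0) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "counts"
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValidationError(
                f"scale must be one of {_VALID_SCALES}, got {self.scale!r}"
            )
        self.values = self.values.astype(float)
        dup_f = _find_duplicates(self.values.index)
        if dup_f:
            raise ValidationError(f"duplicate feature ids: {dup_f}")
        dup_s = _find_duplicates(self.values.columns)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        if self.values.isna().any().any():
            rows = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValidationError(f"missing cells in features {rows[:5]}")
        if self.scale == "counts":
            neg = self.values.lt(0)
            if neg.any().any():
                r = self.values.index[neg.any(axis=1)][0]
                c = self.values.columns[neg.loc[r]][0]
                raise ValidationError(
                    f"negative value {self.values.at[r, c]} at "
                    f"feature {r!r}, sample {c!r} with scale=counts"
                )
        if self.feature_meta is not None:
            missing = self.feature_meta.index.difference(self.values.index)
            if len(missing):
                raise ValidationError(
                    f"feature_meta rows not in table: {list(missing)[:5]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def taxonomy(self) -> pd.Series:
        """Per-feature taxonomy strings; raises if absent."""
        if self.feature_meta is None or TAXONOMY_COLUMN not in self.feature_meta:
            raise ValidationError("feature table carries no taxonomy metadata")
        return self.feature_meta[TAXONOMY_COLUMN].reindex(self.values.index)


@dataclass
class GeneContentMatrix:
    """Predicted per-genome gene content plus 16S rRNA copy numbers.

    ``content`` is an OTU x KO matrix of non-negative gene copy counts;
    ``copy_number`` is the per-OTU 16S rRNA gene copy number used for
    copy-number normalisation (must be strictly positive).
    """

    content: pd.DataFrame
    copy_number: pd.Series

    def __post_init__(self) -> None:
        self.content = self.content.astype(float)
        self.copy_number = self.copy_number.astype(float)
        dup_o = _find_duplicates(self.content.index)
        if dup_o:
            raise ValidationError(f"duplicate OTU ids in gene content: {dup_o}")
        dup_k = _find_duplicates(self.content.columns)
        if dup_k:
            raise ValidationError(f"duplicate KO ids in gene content: {dup_k}")
        if (self.content.to_numpy() < 0).any():
            raise ValidationError("gene content must be non-negative")
        missing = self.content.index.difference(self.copy_number.index)
        if len(missing):
            raise ValidationError(
                f"OTUs missing a 16S copy number: {list(missing)}"
            )
        self.copy_number = self.copy_number.reindex(self.content.index)
        bad = self.copy_number[self.copy_number <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive 16S copy number for OTUs: {list(bad.index)}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.content.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.content.columns)


@dataclass
class PathwayDB:
    """KEGG pathway membership: pathway id -> set of member KO ids."""

    members: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, kos in self.members.items():
            if not kos:
                raise ValidationError(f"pathway {pid!r} has an empty KO set")
        for pid in self.members:
            self.names.setdefault(pid, pid)

    def __len__(self) -> int:
        return len(self.members)

    def pathways_of(self, ko: str) -> list[str]:
        return [p for p, kos in self.members.items() if ko in kos]

    def annotated_kos(self) -> set[str]:
        """All KOs that belong to at least one pathway."""
        out: set[str] = set()
        for kos in self.members.values():
            out |= kos
        return out


@dataclass
class GeneKoMap:
    """Many-to-many host gene -> KO mapping (deduplicated records)."""

    records: pd.DataFrame  # columns: gene_id, ko_id

    def __post_init__(self) -> None:
        if list(self.records.columns) != ["gene_id", "ko_id"]:
            self.records = self.records.rename(
                columns=dict(zip(self.records.columns, ["gene_id", "ko_id"]))
            )
        n0 = len(self.records)
        self.records = self.records.drop_duplicates().reset_index(drop=True)
        if len(self.records) < n0:
            logger.warning(
                "gene->KO map: collapsed %d duplicate records", n0 - len(self.records)
            )

    def kos_for(self, gene: str) -> set[str]:
        return set(self.records.loc[self.records.gene_id == gene, "ko_id"])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Design:
    """Sample grouping plus the ordered pairwise contrasts to test.

    A contrast ``(A, B)`` reads "A vs B" and its log2 fold change is
    ``mean(A) - mean(B)``.  Every sample belongs to exactly one group and
    each contrasted group must hold at least two samples.
    """

    groups: dict[str, str]  # sample_id -> group label
    contrasts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.group_sizes()
        singletons = [g for g, n in sizes.items() if n < 2]
        if singletons:
            raise ValidationError(
                f"groups with fewer than 2 samples: {singletons}"
            )
        for a, b in self.contrasts:
            for g in (a, b):
                if g not in sizes:
                    raise ValidationError(f"contrast group {g!r} has no samples")

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str,
                     encoding="utf-8")
    if df.empty and df.columns.size == 0:
        raise ValidationError(f"{path}: empty file")
    return df


def _check_header_duplicates(path) -> None:
    # pandas mangles duplicate header names; catch them before parsing
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")[1:]
            dup = _find_duplicates(cols)
            if dup:
                raise ValidationError(f"duplicate sample ids: {dup}")
            return


def read_feature_table(path, scale: str = "counts") -> FeatureTable:
    """Read a feature x sample table; a ``taxonomy`` column becomes metadata."""
    _check_header_duplicates(path)
    df = _read_tsv(path)
    idcol = df.columns[0]
    df = df.set_index(idcol)
    df.index = df.index.astype(str)
    meta = None
    if TAXONOMY_COLUMN in df.columns:
        meta = df[[TAXONOMY_COLUMN]].copy()
        df = df.drop(columns=[TAXONOMY_COLUMN])
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    return FeatureTable(values=values, scale=scale, feature_meta=meta)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.values.copy()
    if table.feature_meta is not None and TAXONOMY_COLUMN in table.feature_meta:
        df[TAXONOMY_COLUMN] = table.feature_meta[TAXONOMY_COLUMN].reindex(df.index)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", encoding="utf-8")


def read_gene_content(content_path, copy_number_path) -> GeneContentMatrix:
    """Read the OTU x KO gene-content table and the per-OTU 16S copy numbers."""
    content = _read_tsv(content_path)
    content = content.set_index(content.columns[0])
    content.index = content.index.astype(str)
    content = content.astype(float)
    cn = _read_tsv(copy_number_path)
    if cn.shape[1] < 2:
        raise ValidationError(f"{copy_number_path}: expected two columns")
    copy_number = pd.Series(
        cn.iloc[:, 1].astype(float).to_numpy(),
        index=cn.iloc[:, 0].astype(str),
    )
    dup = _find_duplicates(copy_number.index)
    if dup:
        raise ValidationError(f"duplicate OTU ids in copy-number table: {dup}")
    return GeneContentMatrix(content=content, copy_number=copy_number)


def write_gene_content(gcm: GeneContentMatrix, content_path, copy_number_path) -> None:
    df = gcm.content.copy()
    df.index.name = "otu_id"
    df.to_csv(content_path, sep="\t", encoding="utf-8")
    cn = gcm.copy_number.rename("copy_number").to_frame()
    cn.index.name = "otu_id"
    cn.to_csv(copy_number_path, sep="\t", encoding="utf-8")


def read_pathway_db(path) -> PathwayDB:
    """Read a two/three-column (pathway_id, ko_id[, pathway_name]) file."""
    df = _read_tsv(path)
    if df.empty:
        raise ValidationError(f"{path}: no pathway records")
    n0 = len(df)
    has_name = df.shape[1] >= 3
    keep = df.iloc[:, :2].drop_duplicates()
    if len(keep) < n0:
        logger.warning("pathway db: collapsed %d duplicate records", n0 - len(keep))
    members: dict[str, set[str]] = {}
    for pid, ko in keep.itertuples(index=False):
        members.setdefault(str(pid), set()).add(str(ko))
    names: dict[str, str] = {}
    if has_name:
        for pid, name in zip(df.iloc[:, 0], df.iloc[:, 2]):
            if isinstance(name, str) and name:
                names[str(pid)] = name
    return PathwayDB(members=members, names=names)


def write_pathway_db(db: PathwayDB, path) -> None:
    rows = [
        (pid, ko, db.names.get(pid, pid))
        for pid in sorted(db.members)
        for ko in sorted(db.members[pid])
    ]
    pd.DataFrame(rows, columns=["pathway_id", "ko_id", "pathway_name"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_gene_ko_map(path) -> GeneKoMap:
    df = _read_tsv(path)
    if df.empty:
        raise ValidationError(f"{path}: no gene->KO records")
    rec = df.iloc[:, :2].copy()
    rec.columns = ["gene_id", "ko_id"]
    rec = rec.astype(str)
    return GeneKoMap(records=rec)


def write_gene_ko_map(gkm: GeneKoMap, path) -> None:
    gkm.records.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_design(path, contrasts: list[tuple[str, str]] | None = None) -> Design:
    """Read a two-column (sample_id, group) file; contrasts supplied separately."""
    df = _read_tsv(path)
    if df.empty:
        raise ValidationError(f"{path}: no design records")
    n0 = len(df)
    df = df.iloc[:, :2].drop_duplicates()
    if len(df) < n0:
        logger.warning("design: collapsed %d duplicate records", n0 - len(df))
    samples = df.iloc[:, 0].astype(str)
    dup = _find_duplicates(samples)
    if dup:
        raise ValidationError(f"samples assigned to multiple groups: {dup}")
    groups = dict(zip(samples, df.iloc[:, 1].astype(str)))
    return Design(groups=groups, contrasts=list(contrasts or []))


def write_design(design: Design, path) -> None:
    pd.DataFrame(
        list(design.groups.items()), columns=["sample_id", "group"]
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
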