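"""Projection of differential features into KEGG-orthology (KO) space.

Host genes called differential are mapped through a static gene->KO file
(many-to-many); microbiome KOs come straight from the thresholded
differential result on the inferred KO table.  Either way the product is a
:class:`KoSet` per direction: UP (increased), DOWN (reduced) and ALL, with
provenance tracking which source features put each KO on the list.

A KO reached from both an up- and a down-gene is a direction conflict: it is
kept in ALL, excluded from UP and DOWN, and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .differential import DifferentialResult, select_differential
from .io_formats import GeneKoMap, ValidationError

logger = logging.getLogger("komix.map")

MICROBIOME_SOURCE = "microbiome"


@dataclass
class KoSet:
    """A direction-labelled KO list with per-KO provenance.

    ``provenance`` maps each member KO to the source ids (host gene ids, or
    the literal ``"microbiome"``) that contributed it; ``conflicts`` holds
    KOs hit from both directions (members of ALL only).
    """

    comparison: str
    direction: str  # ALL | UP | DOWN
    kos: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)
    conflicts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.direction not in ("ALL", "UP", "DOWN"):
            raise ValidationError(f"bad direction {self.direction!r}")
        for ko in self.kos:
            if not self.provenance.get(ko):
                raise ValidationError(f"KO {ko!r} has empty provenance")

    @property
    def label(self) -> str:
        return f"{self.comparison}_{self.direction}"

    def __len__(self) -> int:
        return len(self.kos)


def _merge_provenance(*sources: dict[str, set[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for src in sources:
        for ko, ids in src.items():
            out.setdefault(ko, set()).update(ids)
    return out


def map_genes_to_kos(
    genes_up: set[str],
    genes_down: set[str],
    gene_ko_map: GeneKoMap,
    comparison: str,
) -> tuple[KoSet, KoSet, KoSet]:
    """Map up/down host gene sets to (UP, DOWN, ALL) KO sets.

    Unmapped genes are dropped (count logged); KOs reached from both
    directions are flagged as conflicts and kept only in ALL.
    """
    if len(gene_ko_map) == 0:
        raise ValidationError("gene->KO map is empty")
    if genes_up & genes_down:
        raise ValidationError(
            f"genes in both directions: {sorted(genes_up & genes_down)[:5]}"
        )
    rec = gene_ko_map.records
    prov_up: dict[str, set[str]] = {}
    prov_down: dict[str, set[str]] = {}
    unmapped = 0
    for genes, prov in ((genes_up, prov_up), (genes_down, prov_down)):
        hits = rec[rec.gene_id.isin(genes)]
        for gene, ko in hits.itertuples(index=False):
            prov.setdefault(ko, set()).add(gene)
        unmapped += len(genes - set(hits.gene_id))
    if unmapped:
        logger.info("%d differential genes had no KO mapping", unmapped)

    conflicts = set(prov_up) & set(prov_down)
    if conflicts:
        logger.info("%d KOs hit from both directions (kept in ALL only)",
                    len(conflicts))
    up = KoSet(comparison, "UP", set(prov_up) - conflicts,
               {k: v for k, v in prov_up.items() if k not in conflicts})
    down = KoSet(comparison, "DOWN", set(prov_down) - conflicts,
                 {k: v for k, v in prov_down.items() if k not in conflicts})
    all_ = KoSet(comparison, "ALL", set(prov_up) | set(prov_down),
                 _merge_provenance(prov_up, prov_down), conflicts=conflicts)
    return up, down, all_


def kos_from_microbiome(
    diff: DifferentialResult,
    comparison: str,
    contrast: tuple[str, str] | None = None,
) -> tuple[KoSet, KoSet, KoSet]:
    """KO sets from the thresholded differential result on the KO table."""
    up_ids, down_ids = select_differential(diff, contrast)
    prov_up = {k: {MICROBIOME_SOURCE} for k in up_ids}
    prov_down = {k: {MICROBIOME_SOURCE} for k in down_ids}
    up = KoSet(comparison, "UP", set(up_ids), prov_up)
    down = KoSet(comparison, "DOWN", set(down_ids), prov_down)
    all_ = KoSet(comparison, "ALL", set(up_ids) | set(down_ids),
                 _merge_provenance(prov_up, prov_down))
    return up, down, all_
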