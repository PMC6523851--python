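"""EASE-score pathway enrichment and contribution deconvolution.

The EASE score is a conservative variant of the one-sided Fisher exact test
popularised by DAVID: one hit is removed from the overlap cell before
computing the hypergeometric upper tail, so a single-KO overlap can never be
significant (k <= 1 gives p = 1 exactly).  The background universe is, by
default, the set of KOs measured in the relevant dataset that are annotated
to at least one pathway; joint host+microbiome runs use the union of the two
measured universes.

Enriched pathways are deconvoluted into their contributing host transcripts
(via KO provenance) and contributing taxa (via the per-OTU contribution
records of the metagenome prediction, reported at genus level and ordered by
contribution share).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .io_formats import PathwayDB, ValidationError
from .ko_inference import ContributionTable, parse_genus
from .ko_mapping import KoSet, MICROBIOME_SOURCE, _merge_provenance

logger = logging.getLogger("komix.enrich")

#: Fig-style star thresholds on the EASE p-value.
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
DEFAULT_MIN_PATHWAY_SIZE = 3


def stars(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p <= thr:
            return s
    return ""


def ease_score(k: int, n: int, K: int, N: int, penalized: bool = True) -> float:
    """One-sided enrichment p-value with the EASE one-hit penalty.

    Parameters: ``k`` hits in the list, ``n`` list size, ``K`` pathway size
    in the universe, ``N`` universe size.  With the penalty the 2x2 table
    becomes (k-1, n-k, K-k, N-K-n+k) — every margin shrinks by one — and the
    p-value is the hypergeometric upper tail of that table; k <= 1 yields
    p = 1.  ``penalized=False`` gives the plain one-sided Fisher p.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and N >= 0):
        raise ValidationError(
            f"inconsistent enrichment margins k={k} n={n} K={K} N={N}"
        )
    if not penalized:
        return float(hypergeom.sf(k - 1, N, K, n))
    if k <= 1:
        return 1.0
    # upper tail P(X >= k-1) with X ~ Hypergeom(N-1, K-1, n-1)
    return float(hypergeom.sf(k - 2, N - 1, K - 1, n - 1))


@dataclass
class EnrichmentRow:
    """One pathway x comparison x direction enrichment record."""

    pathway_id: str
    pathway_name: str
    comparison: str
    direction: str
    k: int
    K: int
    n: int
    N: int
    p_ease: float
    stars: str
    hit_kos: set[str] = field(default_factory=set)
    contributing_genes: list[tuple[str, str]] = field(default_factory=list)
    contributing_taxa: list[tuple[str, str, float]] = field(default_factory=list)


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Long-format table of enrichment rows (one per pathway x comparison x direction)."""
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "comparison": r.comparison,
                "direction": r.direction,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_ease": r.p_ease,
                "stars": r.stars,
                "hit_kos": ",".join(sorted(r.hit_kos)),
            }
            for r in rows
        ],
        columns=["pathway_id", "pathway_name", "comparison", "direction",
                 "k", "K", "n", "N", "p_ease", "stars", "hit_kos"],
    )


def enrich(
    koset: KoSet,
    db: PathwayDB,
    universe: set[str],
    min_pathway_size: int = DEFAULT_MIN_PATHWAY_SIZE,
    penalized: bool = True,
) -> list[EnrichmentRow]:
    """One EASE test per pathway for a KO list against a background universe.

    Pathway size K counts only universe members; pathways with K below
    ``min_pathway_size`` are skipped.  Rows come back sorted by p-value
    (ties by pathway id).
    """
    if not universe:
        raise ValidationError("empty enrichment universe")
    listed = koset.kos & universe
    outside = koset.kos - universe
    if outside:
        logger.warning("%d listed KOs outside the universe were dropped",
                       len(outside))
    n = len(listed)
    N = len(universe)
    rows: list[EnrichmentRow] = []
    for pid in sorted(db.members):
        measured = db.members[pid] & universe
        K = len(measured)
        if K < min_pathway_size:
            continue
        hits = measured & listed
        k = len(hits)
        p = ease_score(k, n, K, N, penalized=penalized)
        rows.append(
            EnrichmentRow(
                pathway_id=pid,
                pathway_name=db.names.get(pid, pid),
                comparison=koset.comparison,
                direction=koset.direction,
                k=k, K=K, n=n, N=N,
                p_ease=p, stars=stars(p), hit_kos=hits,
            )
        )
    rows.sort(key=lambda r: (r.p_ease, r.pathway_id))
    return rows


def joint_union(host: KoSet, microbiome: KoSet) -> KoSet:
    """Union of host and microbiome KO sets with merged provenance.

    Both sets must carry the same comparison label and direction.  For
    ALL-direction unions, direction conflicts across omics are inherited.
    """
    if host.comparison != microbiome.comparison:
        raise ValidationError(
            f"comparison labels differ: {host.comparison!r} vs "
            f"{microbiome.comparison!r}"
        )
    if host.direction != microbiome.direction:
        raise ValidationError(
            f"directions differ: {host.direction!r} vs {microbiome.direction!r}"
        )
    prov = _merge_provenance(
        {k: v for k, v in host.provenance.items()},
        {k: v for k, v in microbiome.provenance.items()},
    )
    return KoSet(
        comparison=host.comparison,
        direction=host.direction,
        kos=host.kos | microbiome.kos,
        provenance=prov,
        conflicts=host.conflicts | microbiome.conflicts,
    )


def resolve_cross_omics_conflicts(
    host_up: KoSet, host_down: KoSet, host_all: KoSet,
    mic_up: KoSet, mic_down: KoSet, mic_all: KoSet,
) -> tuple[KoSet, KoSet, KoSet]:
    """Join the two omics per direction, demoting cross-omics direction clashes.

    A KO up in one omic and down in the other leaves UP and DOWN and is kept,
    flagged, in ALL — the same policy applied within the host mapping.
    """
    up = joint_union(host_up, mic_up)
    down = joint_union(host_down, mic_down)
    all_ = joint_union(host_all, mic_all)
    clash = up.kos & down.kos
    if clash:
        logger.info("%d KOs clash in direction across omics", len(clash))
        up = KoSet(up.comparison, "UP", up.kos - clash,
                   {k: v for k, v in up.provenance.items() if k not in clash},
                   conflicts=up.conflicts)
        down = KoSet(down.comparison, "DOWN", down.kos - clash,
                     {k: v for k, v in down.provenance.items() if k not in clash},
                     conflicts=down.conflicts)
        all_.conflicts |= clash
    return up, down, all_


def deconvolute_contributors(
    row: EnrichmentRow,
    contributions: ContributionTable | None,
    provenance: dict[str, set[str]],
    gene_directions: dict[str, str] | None = None,
    otu_taxonomy: pd.Series | None = None,
    genus_directions: dict[str, str] | None = None,
) -> EnrichmentRow:
    """Fill a row's contributing host genes and taxa for its hit KOs.

    Genes come from KO provenance (annotated by their own differential
    direction); taxa are the genera of OTUs with nonzero contribution to the
    microbially-measured hit KOs, ordered by total contribution share
    (descending; shares over the pathway sum to 1).
    """
    gene_directions = gene_directions or {}
    genus_directions = genus_directions or {}

    genes: set[str] = set()
    microbial_hits: set[str] = set()
    for ko in row.hit_kos:
        for src in provenance.get(ko, set()):
            if src == MICROBIOME_SOURCE:
                microbial_hits.add(ko)
            else:
                genes.add(src)
    row.contributing_genes = sorted(
        (g, gene_directions.get(g, "ns")) for g in genes
    )

    if microbial_hits:
        if contributions is None:
            raise ValidationError(
                "microbial hit KOs present but no contribution records supplied"
            )
        rec = contributions.for_kos(microbial_hits)
        got = set(rec.ko_id)
        missing = microbial_hits - got
        if missing:
            raise ValidationError(
                f"no contribution records for hit KOs: {sorted(missing)[:5]}"
            )
        if otu_taxonomy is None:
            raise ValidationError("taxa deconvolution needs OTU taxonomy")
        genus = rec.otu_id.map(lambda o: parse_genus(otu_taxonomy[o]))
        totals = rec.groupby(genus)["contribution"].sum().sort_values(
            ascending=False
        )
        total = float(totals.sum())
        row.contributing_taxa = [
            (g, genus_directions.get(g, "ns"), float(v) / total)
            for g, v in totals.items()
            if v > 0
        ]
    return row


def table2_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Deconvolution report: pathway | genes | microbes | comparison_direction.

    Microbes are ordered by contribution share from high to low.
    """
    out = []
    for r in rows:
        out.append(
            {
                "pathway": r.pathway_name,
                "genes": ", ".join(g for g, _ in r.contributing_genes),
                "microbes": ", ".join(t for t, _, _ in r.contributing_taxa),
                "comparison_direction": f"{r.comparison}_{r.direction}",
                "p_ease": r.p_ease,
                "stars": r.stars,
            }
        )
    return pd.DataFrame(
        out, columns=["pathway", "genes", "microbes",
                      "comparison_direction", "p_ease", "stars"]
    )
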