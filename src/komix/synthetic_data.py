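"""Synthetic host-microbiome studies with planted ground truth.

Emulates the data shapes of a paired 16S + host-transcriptome study of four
treatment arms (healthy control, induced arthritis, mechanical stimulation,
methotrexate + mechanical stimulation): negative-binomial OTU counts with
log-normal baseline abundances, a sparse integer OTU x KO gene-content
matrix with 16S copy numbers, gaussian log2 host expression, a many-to-many
gene->KO map and a KEGG-style pathway membership file.

Ground truth is planted at three levels and recorded in a
:class:`TruthManifest`:

* differential OTUs — group means multiplied by ``2**effect_log2`` in one
  arm of a contrast;
* differential host genes — log2 expression shifted by the effect in one arm;
* enriched pathways — realised as *cassettes*: a pathway whose member KOs are
  carried exclusively by a dedicated set of planted OTUs (one genus each) and
  targeted by dedicated planted host genes, so the pathway must surface in
  the joint enrichment and its deconvolution must name exactly those genera
  and genes.

A single integer seed fully determines every emitted table; per-stage
substreams are derived from it with ``numpy`` SeedSequence spawning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Design,
    FeatureTable,
    GeneContentMatrix,
    GeneKoMap,
    PathwayDB,
    ValidationError,
    write_design,
    write_feature_table,
    write_gene_content,
    write_gene_ko_map,
    write_pathway_db,
)

DEFAULT_GROUPS = ("NOCIA", "CIA", "MS", "MTXMS")
DEFAULT_CONTRASTS = (
    ("NOCIA", "CIA"),
    ("MS", "CIA"),
    ("MTXMS", "CIA"),
    ("MS", "MTXMS"),
)

#: Genus pool for taxonomy strings; the front of the list is reserved for
#: planted cassette OTUs so each cassette member is its own genus.
GENUS_POOL = [
    "Akkermansia", "Prevotella", "Lactobacillus", "Oscillospira",
    "Turicibacter", "Allobaculum", "Parabacteroides", "Moryella",
    "Bacteroides", "Ruminococcus", "Clostridium", "Blautia",
    "Coprococcus", "Dorea", "Faecalibacterium", "Roseburia",
    "Sutterella", "Bifidobacterium", "Desulfovibrio", "Anaerostipes",
]

_FAMILIES = ["Lachnospiraceae", "Ruminococcaceae", "S24-7",
             "Bacteroidaceae", "Lactobacillaceae", "Clostridiaceae"]


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class TruthManifest:
    """Planted ground truth of one synthetic study."""

    seed: int
    planted_diff_otus: list[tuple[str, str, float]] = field(default_factory=list)
    planted_diff_genes: list[tuple[str, str, float]] = field(default_factory=list)
    planted_pathways: list[tuple[str, str, str]] = field(default_factory=list)
    cassette_otus: dict[str, list[str]] = field(default_factory=dict)
    cassette_kos: dict[str, list[str]] = field(default_factory=dict)
    cassette_genera: dict[str, list[str]] = field(default_factory=dict)
    cassette_genes: dict[str, list[str]] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("seed", str(self.seed), "", "", "")]
        for k, v in sorted(self.params.items()):
            rows.append(("param", k, "", "", repr(v)))
        for otu, contrast, eff in self.planted_diff_otus:
            rows.append(("otu", otu, contrast, "up" if eff > 0 else "down",
                         repr(eff)))
        for gene, contrast, eff in self.planted_diff_genes:
            rows.append(("gene", gene, contrast, "up" if eff > 0 else "down",
                         repr(eff)))
        for pid, contrast, direction in self.planted_pathways:
            rows.append(("pathway", pid, contrast, direction, ""))
        for pid in self.cassette_otus:
            for otu in self.cassette_otus[pid]:
                rows.append(("cassette_otu", otu, "", "", pid))
            for ko in self.cassette_kos[pid]:
                rows.append(("cassette_ko", ko, "", "", pid))
            for g in self.cassette_genera[pid]:
                rows.append(("cassette_genus", g, "", "", pid))
            for g in self.cassette_genes.get(pid, []):
                rows.append(("cassette_gene", g, "", "", pid))
        return pd.DataFrame(
            rows, columns=["kind", "id", "comparison", "direction", "extra"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


@dataclass
class StudyConfig:
    """Generator parameters; defaults are the package's study conditions."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    n_per_group: int = 5
    n_otus: int = 200
    n_kos: int = 400
    n_genes: int = 800
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (8, 25)
    n_planted_pathways: int = 3
    cassette_size: int = 12          # KOs per planted pathway
    cassette_otus: int = 4           # planted OTUs carrying each cassette
    cassette_genes: int = 4          # planted host genes per cassette
    n_planted_otus: int = 10         # free-standing planted OTUs
    n_planted_genes: int = 20        # free-standing planted genes
    effect_log2: float = 2.0
    dispersion: float = 0.1          # NB variance mu + alpha*mu^2
    depth: int = 15000               # reads per sample
    noise_sd: float = 0.5            # expression log2 noise
    content_sparsity: float = 0.9
    copy_number_range: tuple[int, int] = (1, 7)
    shared_ko_fraction: float = 0.5  # host genes mapping into microbial KOs
    n_host_only_kos: int = 200


def _taxonomy_string(genus: str, family: str) -> str:
    return (
        "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
        f"f__{family};g__{genus};s__"
    )


def _make_design(groups, n_per_group, contrasts) -> Design:
    samples = {
        f"{g}_{i + 1}": g for g in groups for i in range(n_per_group)
    }
    return Design(groups=samples, contrasts=list(contrasts))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_community(
    n_otus: int,
    groups=DEFAULT_GROUPS,
    n_per_group: int = 5,
    n_planted: int = 10,
    effect_log2: float = 2.0,
    dispersion: float = 0.1,
    depth: int = 15000,
    seed: int = 0,
    contrasts=DEFAULT_CONTRASTS,
    planted: list[tuple[int, int, int]] | None = None,
    reserved_genera: dict[int, str] | None = None,
) -> tuple[FeatureTable, TruthManifest]:
    """Negative-binomial OTU counts with planted group effects.

    ``planted`` optionally pins (otu_index, contrast_index, sign) triples;
    otherwise ``n_planted`` OTUs are drawn at random and cycled over the
    contrasts with alternating signs.  A planted "up" OTU has its mean
    multiplied by ``2**effect_log2`` in the first group of its contrast, a
    "down" OTU in the second; group compositions are renormalised so column
    depths stay at ``depth``.  ``reserved_genera`` pins specific OTUs to
    dedicated genera (used for pathway cassettes).
    """
    if n_planted > n_otus:
        raise ValidationError("n_planted exceeds n_otus")
    rng = _rng(seed, 0)
    groups = list(groups)
    contrasts = list(contrasts)
    otu_ids = [f"OTU_{i + 1}" for i in range(n_otus)]

    # log-normal baseline relative abundances
    log_base = rng.normal(0.0, 1.5, size=n_otus)

    if planted is None:
        planted = []
        if effect_log2 != 0 and n_planted > 0:
            idx = rng.choice(n_otus, size=n_planted, replace=False)
            planted = [
                (int(i), j % len(contrasts), 1 if j % 2 == 0 else -1)
                for j, i in enumerate(idx)
            ]
    # planted OTUs are seeded at >= median baseline so the effect is
    # identifiable at the configured depth
    med = float(np.median(log_base))
    for i, _, _ in planted:
        if log_base[i] < med:
            log_base[i] = med + abs(log_base[i] - med) * 0.25

    base = np.exp(log_base)
    mult = np.ones((n_otus, len(groups)))
    manifest = TruthManifest(seed=seed)
    for i, ci, sign in planted:
        a, b = contrasts[ci]
        target = a if sign > 0 else b
        mult[i, groups.index(target)] *= 2.0 ** effect_log2
        manifest.planted_diff_otus.append(
            (otu_ids[i], f"{a}-{b}", sign * effect_log2)
        )

    counts = np.zeros((n_otus, len(groups) * n_per_group), dtype=float)
    sample_ids = []
    col = 0
    for gi, g in enumerate(groups):
        w = base * mult[:, gi]
        mu = depth * w / w.sum()
        for r in range(n_per_group):
            counts[:, col] = _nb_draw(rng, mu, dispersion)
            sample_ids.append(f"{g}_{r + 1}")
            col += 1

    # taxonomy: several OTUs per genus; ~5% get an empty genus field
    reserved = reserved_genera or {}
    n_background_genera = max(1, n_otus // 4)
    pool = [
        g for g in GENUS_POOL if g not in reserved.values()
    ] + [f"Genus{i:03d}" for i in range(max(0, n_background_genera - 20))]
    pool = pool[:n_background_genera]
    genus_idx = rng.integers(0, len(pool), size=n_otus)
    no_genus = rng.random(n_otus) < 0.05
    taxa = []
    for i in range(n_otus):
        fam = _FAMILIES[int(genus_idx[i]) % len(_FAMILIES)]
        if i in reserved:
            taxa.append(_taxonomy_string(reserved[i], fam))
        elif no_genus[i]:
            taxa.append(_taxonomy_string("", fam))
        else:
            taxa.append(_taxonomy_string(pool[int(genus_idx[i])], fam))

    table = FeatureTable(
        values=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        scale="counts",
        feature_meta=pd.DataFrame({"taxonomy": taxa}, index=otu_ids),
    )
    manifest.params.update(
        n_otus=n_otus, effect_log2=effect_log2, dispersion=dispersion,
        depth=depth, n_per_group=n_per_group,
    )
    return table, manifest


def generate_gene_content(
    otu_ids: list[str],
    n_kos: int,
    sparsity: float = 0.9,
    copy_number_range: tuple[int, int] = (1, 7),
    seed: int = 0,
    cassettes: list[tuple[list[str], list[str]]] | None = None,
) -> GeneContentMatrix:
    """Sparse integer OTU x KO gene content plus uniform 16S copy numbers.

    ``cassettes`` is a list of (cassette_ko_ids, cassette_otu_ids) pairs:
    those KO columns get content *only* in their cassette OTUs (every
    cassette cell >= 1), making the cassette OTUs the sole contributors of
    those KOs downstream.
    """
    if not 0 <= sparsity < 1:
        raise ValidationError("sparsity must be in [0, 1)")
    rng = _rng(seed, 1)
    ko_ids = [f"K{i + 1:05d}" for i in range(n_kos)]
    n_otus = len(otu_ids)
    mask = rng.random((n_otus, n_kos)) >= sparsity
    content = np.where(mask, rng.integers(1, 4, size=(n_otus, n_kos)), 0)

    df = pd.DataFrame(content.astype(float), index=otu_ids, columns=ko_ids)
    if cassettes:
        otu_pos = {o: i for i, o in enumerate(otu_ids)}
        for kos, otus in cassettes:
            missing = [k for k in kos if k not in df.columns]
            if missing:
                raise ValidationError(f"cassette KOs not in KO range: {missing}")
            df.loc[:, kos] = 0.0
            for o in otus:
                if o not in otu_pos:
                    raise ValidationError(f"cassette OTU {o!r} unknown")
                df.loc[o, kos] = rng.integers(1, 4, size=len(kos)).astype(float)

    lo, hi = copy_number_range
    copy_number = pd.Series(
        rng.integers(lo, hi + 1, size=n_otus).astype(float), index=otu_ids
    )
    return GeneContentMatrix(content=df, copy_number=copy_number)


def generate_expression(
    n_genes: int,
    groups=DEFAULT_GROUPS,
    n_per_group: int = 5,
    n_planted: int = 20,
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    contrasts=DEFAULT_CONTRASTS,
    planted: list[tuple[int, int, int]] | None = None,
    ko_pool: list[str] | None = None,
    host_only_kos: int = 200,
    shared_ko_fraction: float = 0.5,
    pinned_kos: dict[int, str] | None = None,
) -> tuple[FeatureTable, GeneKoMap, TruthManifest]:
    """Gaussian log2 host expression with planted shifts, plus a gene->KO map.

    Planted genes are shifted by the effect in one arm of their contrast.
    Each gene maps to 1-3 KOs; with probability ``shared_ko_fraction`` a KO
    is drawn from the microbial ``ko_pool`` (making joint analysis
    non-trivial), otherwise from a host-only pool.  ``pinned_kos`` forces a
    gene's first KO (used to tie planted genes to pathway cassettes).
    """
    if n_planted > n_genes:
        raise ValidationError("n_planted exceeds n_genes")
    rng = _rng(seed, 2)
    groups = list(groups)
    contrasts = list(contrasts)
    gene_ids = [f"Gene{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"{g}_{r + 1}" for g in groups for r in range(n_per_group)]

    base = rng.normal(7.0, 2.0, size=n_genes)
    shift = np.zeros((n_genes, len(groups)))
    manifest = TruthManifest(seed=seed)
    if planted is None:
        planted = []
        if effect_log2 != 0 and n_planted > 0:
            idx = rng.choice(n_genes, size=n_planted, replace=False)
            planted = [
                (int(i), j % len(contrasts), 1 if j % 2 == 0 else -1)
                for j, i in enumerate(idx)
            ]
    for i, ci, sign in planted:
        a, b = contrasts[ci]
        target = a if sign > 0 else b
        shift[i, groups.index(target)] += effect_log2
        manifest.planted_diff_genes.append(
            (gene_ids[i], f"{a}-{b}", sign * effect_log2)
        )

    values = np.empty((n_genes, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        gi = groups.index(s.rsplit("_", 1)[0])
        values[:, j] = base + shift[:, gi] + rng.normal(0, noise_sd, n_genes)

    table = FeatureTable(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        scale="log2",
    )

    ko_pool = list(ko_pool or [])
    host_pool = [f"K9{i + 1:04d}" for i in range(host_only_kos)]
    pinned_kos = pinned_kos or {}
    records = []
    for i, g in enumerate(gene_ids):
        kos: list[str] = []
        if i in pinned_kos:
            kos.append(pinned_kos[i])
        n_extra = int(rng.integers(1, 4)) - len(kos)
        for _ in range(max(n_extra, 0)):
            if ko_pool and rng.random() < shared_ko_fraction:
                kos.append(ko_pool[int(rng.integers(0, len(ko_pool)))])
            else:
                kos.append(host_pool[int(rng.integers(0, len(host_pool)))])
        records.extend((g, k) for k in dict.fromkeys(kos))
    gkm = GeneKoMap(records=pd.DataFrame(records, columns=["gene_id", "ko_id"]))
    manifest.params.update(n_genes=n_genes, noise_sd=noise_sd,
                           effect_log2=effect_log2)
    return table, gkm, manifest


@dataclass
class StudyBundle:
    """All in-memory inputs of one synthetic study."""

    otu_table: FeatureTable
    gene_content: GeneContentMatrix
    pathway_db: PathwayDB
    expression: FeatureTable
    gene_ko_map: GeneKoMap
    design: Design
    truth: TruthManifest


def generate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> StudyBundle:
    """Generate a complete synthetic study; optionally write it to disk.

    Planted pathways are realised as cassettes: each planted pathway's
    members are exactly its cassette KOs, carried only by its cassette OTUs
    (one dedicated genus each) and targeted by its planted host genes, all
    shifted in the same contrast and direction.
    """
    cfg = config or StudyConfig()
    if cfg.n_planted_pathways * cfg.cassette_size > cfg.n_kos:
        raise ValidationError("cassette KOs exceed the KO space")
    if cfg.cassette_size < 2:
        raise ValidationError("planted pathway smaller than the minimum hits")
    rng = _rng(seed, 3)
    contrasts = list(cfg.contrasts)
    groups = list(cfg.groups)
    ko_ids = [f"K{i + 1:05d}" for i in range(cfg.n_kos)]

    # ---- plant pathways: choose cassette KOs, OTUs, genes, contrast, sign
    truth = TruthManifest(seed=seed)
    all_cassette_kos: list[str] = []
    cassettes = []
    planted_otus: list[tuple[int, int, int]] = []
    pinned_gene_kos: dict[int, str] = {}
    planted_genes: list[tuple[int, int, int]] = []
    reserved_genera: dict[int, str] = {}
    otu_cursor = 0
    gene_cursor = 0
    for p in range(cfg.n_planted_pathways):
        pid = f"path_planted{p + 1:02d}"
        kos = ko_ids[p * cfg.cassette_size:(p + 1) * cfg.cassette_size]
        otus = [f"OTU_{otu_cursor + i + 1}" for i in range(cfg.cassette_otus)]
        ci = p % len(contrasts)
        sign = 1 if p % 2 == 0 else -1
        a, b = contrasts[ci]
        direction = "up" if sign > 0 else "down"
        for i in range(cfg.cassette_otus):
            planted_otus.append((otu_cursor + i, ci, sign))
            reserved_genera[otu_cursor + i] = GENUS_POOL[
                (p * cfg.cassette_otus + i) % len(GENUS_POOL)
            ]
        genes = []
        for i in range(cfg.cassette_genes):
            planted_genes.append((gene_cursor + i, ci, sign))
            pinned_gene_kos[gene_cursor + i] = kos[i % len(kos)]
            genes.append(f"Gene{gene_cursor + i + 1:04d}")
        truth.planted_pathways.append((pid, f"{a}-{b}", direction))
        truth.cassette_otus[pid] = otus
        truth.cassette_kos[pid] = list(kos)
        truth.cassette_genera[pid] = [
            reserved_genera[otu_cursor + i] for i in range(cfg.cassette_otus)
        ]
        truth.cassette_genes[pid] = genes
        cassettes.append((list(kos), otus))
        all_cassette_kos.extend(kos)
        otu_cursor += cfg.cassette_otus
        gene_cursor += cfg.cassette_genes

    # free-standing planted OTUs / genes, cycled over contrasts
    n_free_otus = min(cfg.n_planted_otus, cfg.n_otus - otu_cursor)
    free = rng.choice(
        np.arange(otu_cursor, cfg.n_otus), size=n_free_otus, replace=False
    )
    planted_otus += [
        (int(i), j % len(contrasts), 1 if j % 2 == 0 else -1)
        for j, i in enumerate(free)
    ]
    n_free_genes = min(cfg.n_planted_genes, cfg.n_genes - gene_cursor)
    free_g = rng.choice(
        np.arange(gene_cursor, cfg.n_genes), size=n_free_genes, replace=False
    )
    planted_genes += [
        (int(i), j % len(contrasts), 1 if j % 2 == 0 else -1)
        for j, i in enumerate(free_g)
    ]

    if cfg.effect_log2 == 0:
        planted_otus, planted_genes = [], []
        pinned_gene_kos = {}
        truth = TruthManifest(seed=seed)

    otu_table, m_otu = generate_community(
        cfg.n_otus, groups, cfg.n_per_group,
        effect_log2=cfg.effect_log2, dispersion=cfg.dispersion,
        depth=cfg.depth, seed=seed, contrasts=contrasts,
        planted=planted_otus, reserved_genera=reserved_genera,
    )
    gcm = generate_gene_content(
        otu_table.feature_ids, cfg.n_kos, cfg.content_sparsity,
        cfg.copy_number_range, seed=seed,
        cassettes=cassettes if cfg.effect_log2 != 0 else None,
    )
    expression, gkm, m_gene = generate_expression(
        cfg.n_genes, groups, cfg.n_per_group,
        effect_log2=cfg.effect_log2, noise_sd=cfg.noise_sd, seed=seed,
        contrasts=contrasts, planted=planted_genes,
        ko_pool=ko_ids, host_only_kos=cfg.n_host_only_kos,
        shared_ko_fraction=cfg.shared_ko_fraction,
        pinned_kos=pinned_gene_kos,
    )
    truth.planted_diff_otus = m_otu.planted_diff_otus
    truth.planted_diff_genes = m_gene.planted_diff_genes
    truth.params.update(m_otu.params)
    truth.params.update(m_gene.params)

    # ---- pathway database: planted pathways are exactly their cassettes;
    # background pathways draw from non-cassette microbial + host-only KOs
    members: dict[str, set[str]] = {}
    for pid, kos in truth.cassette_kos.items():
        members[pid] = set(kos)
    background_pool = [k for k in ko_ids if k not in set(all_cassette_kos)]
    background_pool += [f"K9{i + 1:04d}" for i in range(cfg.n_host_only_kos)]
    lo, hi = cfg.pathway_size_range
    for p in range(cfg.n_pathways - len(members)):
        size = int(rng.integers(lo, hi + 1))
        pick = rng.choice(len(background_pool), size=size, replace=False)
        members[f"path_bg{p + 1:03d}"] = {background_pool[i] for i in pick}
    db = PathwayDB(members=members)

    design = _make_design(groups, cfg.n_per_group, contrasts)
    for k, v in dataclasses.asdict(cfg).items():
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            truth.params.setdefault(k, v)

    bundle = StudyBundle(
        otu_table=otu_table, gene_content=gcm, pathway_db=db,
        expression=expression, gene_ko_map=gkm, design=design, truth=truth,
    )
    if outdir is not None:
        write_study(bundle, outdir)
    return bundle


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all bundle tables in the formats io_formats reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": out / "otu_table.tsv",
        "gene_content": out / "gene_content.tsv",
        "copy_numbers": out / "copy_numbers.tsv",
        "pathways": out / "pathways.tsv",
        "expression": out / "expression.tsv",
        "gene2ko": out / "gene2ko.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
    }
    write_feature_table(bundle.otu_table, paths["otu_table"])
    write_gene_content(bundle.gene_content, paths["gene_content"],
                       paths["copy_numbers"])
    write_pathway_db(bundle.pathway_db, paths["pathways"])
    write_feature_table(bundle.expression, paths["expression"])
    write_gene_ko_map(bundle.gene_ko_map, paths["gene2ko"])
    write_design(bundle.design, paths["design"])
    bundle.truth.write(paths["truth"])
    return paths
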