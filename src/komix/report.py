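"""End-to-end pipeline orchestration and report rendering.

``analyze_study`` runs the whole chain in memory — copy-number
normalisation, KO prediction, pathway collapse, genus aggregation, the four
differential analyses (OTU, genus, KO, host expression), gene->KO mapping,
per-direction EASE enrichment on the microbiome, host and joint KO sets, and
deconvolution of significant joint pathways into contributing genes and
genera.  ``run_pipeline`` wraps it with config parsing, file IO, a run
manifest (config hash, versions, filter counts) and a log.

Background universes follow the DAVID/EASE "population" convention: the KOs
measured in the relevant dataset that are annotated to at least one pathway;
joint runs use the union of the two measured universes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import (
    DifferentialResult,
    contrast_label,
    run_differential,
    select_differential,
    write_differential,
)
from .enrichment import (
    EnrichmentRow,
    deconvolute_contributors,
    enrich,
    enrichment_frame,
    resolve_cross_omics_conflicts,
    table2_frame,
)
from .io_formats import (
    Design,
    ValidationError,
    read_design,
    read_feature_table,
    read_gene_content,
    read_gene_ko_map,
    read_pathway_db,
    write_feature_table,
)
from .ko_inference import (
    aggregate_to_genus,
    collapse_to_pathways,
    normalize_by_copy_number,
    predict_metagenome,
)
from .ko_mapping import kos_from_microbiome, map_genes_to_kos
from .synthetic_data import StudyBundle, StudyConfig, generate_study, write_study

logger = logging.getLogger("komix.run")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending ids."""


@dataclass
class Thresholds:
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    strict_p: bool = False
    ci_level: float = 0.95
    min_pathway_size: int = 3
    ease_penalized: bool = True


@dataclass
class StudyResults:
    """Every intermediate and final product of one pipeline run."""

    ko_table: object
    contributions: object
    pathway_table: object
    genus_table: object
    diff_otu: DifferentialResult
    diff_genus: DifferentialResult
    diff_ko: DifferentialResult
    diff_expression: DifferentialResult
    enrichment_microbiome: list[EnrichmentRow] = field(default_factory=list)
    enrichment_host: list[EnrichmentRow] = field(default_factory=list)
    enrichment_joint: list[EnrichmentRow] = field(default_factory=list)
    joint_significant: list[EnrichmentRow] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValidationError, ValueError, KeyError) as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def analyze_study(bundle: StudyBundle, thresholds: Thresholds | None = None) -> StudyResults:
    """Run the full host-microbiome joint analysis on an in-memory study."""
    th = thresholds or Thresholds()
    diff_kw = dict(
        p_threshold=th.p_threshold, lfc_threshold=th.lfc_threshold,
        strict_p=th.strict_p, ci_level=th.ci_level,
    )
    design: Design = bundle.design
    contrasts = list(design.contrasts)
    if not contrasts:
        raise PipelineError("stage 'design' failed: no contrasts configured")

    norm = _stage("normalize")(normalize_by_copy_number,
                               bundle.otu_table, bundle.gene_content)
    ko_table, contributions = _stage("predict")(
        predict_metagenome, norm, bundle.gene_content
    )
    pathway_table = _stage("collapse")(
        collapse_to_pathways, ko_table, bundle.pathway_db
    )
    genus_table = _stage("genus")(aggregate_to_genus, bundle.otu_table)

    diff_otu = _stage("diff-otu")(
        run_differential, bundle.otu_table, design, contrasts, **diff_kw)
    diff_genus = _stage("diff-genus")(
        run_differential, genus_table, design, contrasts, **diff_kw)
    diff_ko = _stage("diff-ko")(
        run_differential, ko_table, design, contrasts, **diff_kw)
    diff_expr = _stage("diff-expression")(
        run_differential, bundle.expression, design, contrasts, **diff_kw)

    annotated = bundle.pathway_db.annotated_kos()
    mic_universe = set(ko_table.values.index) & annotated
    measured_genes = set(bundle.expression.values.index)
    rec = bundle.gene_ko_map.records
    host_measured_kos = set(rec.loc[rec.gene_id.isin(measured_genes), "ko_id"])
    host_universe = host_measured_kos & annotated
    joint_universe = mic_universe | host_universe

    res = StudyResults(
        ko_table=ko_table, contributions=contributions,
        pathway_table=pathway_table, genus_table=genus_table,
        diff_otu=diff_otu, diff_genus=diff_genus, diff_ko=diff_ko,
        diff_expression=diff_expr,
    )
    res.counts.update(
        n_otus=bundle.otu_table.shape[0],
        n_kos_predicted=ko_table.shape[0],
        n_pathways_measured=pathway_table.shape[0],
        n_genera=genus_table.shape[0],
        n_genes=bundle.expression.shape[0],
        universe_microbiome=len(mic_universe),
        universe_host=len(host_universe),
        universe_joint=len(joint_universe),
    )

    for contrast in contrasts:
        label = contrast_label(contrast)
        mic_up, mic_down, mic_all = _stage("map-microbiome")(
            kos_from_microbiome, diff_ko, label, contrast)
        genes_up, genes_down = select_differential(diff_expr, contrast)
        host_up, host_down, host_all = _stage("map-host")(
            map_genes_to_kos, genes_up, genes_down, bundle.gene_ko_map, label)

        for ks in (mic_up, mic_down, mic_all):
            if mic_universe:
                res.enrichment_microbiome += enrich(
                    ks, bundle.pathway_db, mic_universe,
                    th.min_pathway_size, th.ease_penalized)
        for ks in (host_all, host_up, host_down):
            if host_universe:
                res.enrichment_host += enrich(
                    ks, bundle.pathway_db, host_universe,
                    th.min_pathway_size, th.ease_penalized)

        j_up, j_down, j_all = _stage("joint")(
            resolve_cross_omics_conflicts,
            host_up, host_down, host_all, mic_up, mic_down, mic_all)
        gene_dirs = dict(zip(
            diff_expr.for_contrast(contrast).feature,
            diff_expr.for_contrast(contrast).direction))
        genus_dirs = dict(zip(
            diff_genus.for_contrast(contrast).feature,
            diff_genus.for_contrast(contrast).direction))
        tax = bundle.otu_table.taxonomy()
        for ks in (j_all, j_up, j_down):
            rows = enrich(ks, bundle.pathway_db, joint_universe,
                          th.min_pathway_size, th.ease_penalized)
            res.enrichment_joint += rows
            for row in rows:
                if row.p_ease <= th.p_threshold and row.k >= 2:
                    row = _stage("deconvolute")(
                        deconvolute_contributors, row, contributions,
                        ks.provenance, gene_dirs, tax, genus_dirs)
                    res.joint_significant.append(row)

    res.counts.update(
        joint_significant=len(res.joint_significant),
        diff_otu_called=int((diff_otu.table.direction != "ns").sum()),
        diff_gene_called=int((diff_expr.table.direction != "ns").sum()),
        diff_ko_called=int((diff_ko.table.direction != "ns").sum()),
    )
    return res


def render_significance_matrix(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Pathways x (comparison, direction) matrix of EASE p with stars."""
    frame = enrichment_frame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["pathway"])
    frame["column"] = frame.comparison + "_" + frame.direction
    frame["cell"] = frame.apply(
        lambda r: f"{r.p_ease:.3g}{r.stars}", axis=1)
    mat = frame.pivot_table(index="pathway_name", columns="column",
                            values="cell", aggfunc="first")
    mat = mat.sort_index().fillna("")
    mat.index.name = "pathway"
    mat.columns.name = None
    return mat.reset_index()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    if "inputs" not in cfg and "simulate" not in cfg:
        raise ValidationError("config needs an 'inputs' or 'simulate' section")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _load_bundle_from_inputs(inputs: dict, design: Design) -> StudyBundle:
    from .synthetic_data import TruthManifest

    return StudyBundle(
        otu_table=read_feature_table(inputs["otu_table"], scale="counts"),
        gene_content=read_gene_content(inputs["gene_content"],
                                       inputs["copy_numbers"]),
        pathway_db=read_pathway_db(inputs["pathways"]),
        expression=read_feature_table(inputs["expression"], scale="log2"),
        gene_ko_map=read_gene_ko_map(inputs["gene2ko"]),
        design=design,
        truth=TruthManifest(seed=-1),
    )


def write_results(res: StudyResults, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(res.ko_table, out / "ko_table.tsv")
    write_feature_table(res.pathway_table, out / "pathway_table.tsv")
    write_feature_table(res.genus_table, out / "genus_table.tsv")
    res.contributions.records.to_csv(
        out / "contributions.tsv", sep="\t", index=False,
        float_format="%.10g", encoding="utf-8")
    for name, diff in (
        ("diff_otu", res.diff_otu), ("diff_genus", res.diff_genus),
        ("diff_ko", res.diff_ko), ("diff_expression", res.diff_expression),
    ):
        write_differential(diff, out / f"{name}.tsv")
    for name, rows in (
        ("enrichment_microbiome", res.enrichment_microbiome),
        ("enrichment_host", res.enrichment_host),
        ("enrichment_joint", res.enrichment_joint),
    ):
        enrichment_frame(rows).to_csv(
            out / f"{name}.tsv", sep="\t", index=False,
            float_format="%.10g", encoding="utf-8")
        render_significance_matrix(rows).to_csv(
            out / f"{name}_matrix.tsv", sep="\t", index=False,
            encoding="utf-8")
    table2_frame(res.joint_significant).to_csv(
        out / "joint_deconvolution.tsv", sep="\t", index=False,
        float_format="%.10g", encoding="utf-8")


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the whole pipeline from a config mapping or YAML path.

    Writes all result tables, a ``manifest.json`` (package version, config
    hash, record counts at every stage) and ``run.log`` into ``outdir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    root = logging.getLogger("komix")
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        seed = int(config.get("seed", 0))
        th = Thresholds(**config.get("thresholds", {}))
        contrasts = [tuple(c) for c in config.get("contrasts", [])]

        if "simulate" in config:
            sim = dict(config["simulate"] or {})
            if "contrasts" not in sim and contrasts:
                sim["contrasts"] = tuple(contrasts)
            if "groups" in sim:
                sim["groups"] = tuple(sim["groups"])
            if "contrasts" in sim:
                sim["contrasts"] = tuple(tuple(c) for c in sim["contrasts"])
            cfg_obj = StudyConfig(**sim)
            bundle = _stage("simulate")(generate_study, cfg_obj, seed)
            write_study(bundle, out / "simulated")
            if not contrasts:
                contrasts = list(bundle.design.contrasts)
        else:
            inputs = config["inputs"]
            design = read_design(inputs["design"], contrasts=contrasts)
            bundle = _stage("load")(_load_bundle_from_inputs, inputs, design)
        missing = [c for pair in contrasts for c in pair
                   if c not in set(bundle.design.groups.values())]
        if missing:
            raise PipelineError(
                f"stage 'design' failed: contrast groups not in design: "
                f"{sorted(set(missing))}")
        bundle.design.contrasts = contrasts

        logger.info("config hash %s", _config_hash(config))
        res = analyze_study(bundle, th)
        write_results(res, out)

        manifest = {
            "komix_version": __version__,
            "config_hash": _config_hash(config),
            "seed": seed,
            "thresholds": dataclass_dict(th),
            "counts": res.counts,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def dataclass_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)
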