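"""End-to-end orchestration: read inputs, map interologs, score evidence,
analyze topology, predict functions, and export the result tables."""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import yaml

from . import io_formats
from .evidence import ScoringConfig, score_all, tier_counts
from .function_prediction import predict_functions
from .interolog import (
    filter_by_miscore,
    integrate_curated,
    map_interologs,
    species_support_histogram,
)
from .network import (
    build_network,
    class_histogram,
    network_summary,
)
from .synthetic import DEFAULT_SPECIES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    bundle_dir: str
    output_dir: str
    species: tuple[str, ...] = DEFAULT_SPECIES
    mi_threshold: float = 0.0
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    top_k: int = 5
    gba_holdout: float = 0.1
    seed: int = 0
    curated_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.mi_threshold <= 1.0):
            raise ValueError("mi_threshold outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        scoring = ScoringConfig(**raw.pop("scoring", {}))
        species = tuple(raw.pop("species", DEFAULT_SPECIES))
        curated = tuple(tuple(p) for p in raw.pop("curated_pairs", ()))
        return cls(species=species, scoring=scoring, curated_pairs=curated, **raw)


@dataclass
class RunReport:
    n_total: int = 0
    n_self: int = 0
    n_hetero: int = 0
    n_curated_overlap: int = 0
    n_curated_added: int = 0
    tier_counts: dict = field(default_factory=dict)
    score_histogram: dict = field(default_factory=dict)
    species_support_histogram: dict = field(default_factory=dict)
    node_class_histogram: dict = field(default_factory=dict)
    n_proteins: int = 0
    largest_component_size: int = 0
    average_partners: int = 0
    n_unannotated: int = 0
    n_unannotated_predicted: int = 0


def _load_bundle(config: PipelineConfig):
    bundle = Path(config.bundle_dir)
    species = [s for s in config.species if (bundle / f"refppi_{s}.tsv").exists()]
    ref_ppis = []
    for s in species:
        ref_ppis.extend(io_formats.read_mitab(bundle / f"refppi_{s}.tsv", s))
    omap = io_formats.read_ortholog_map(bundle / "orthologs.tsv", species)
    dag = io_formats.read_obo(bundle / "ontology.obo")
    annotations = io_formats.read_gaf(bundle / "annotations.gaf", dag)
    tables = io_formats.read_evidence_tables(
        bundle / "domains.tsv", bundle / "ddi.tsv", bundle / "localization.tsv"
    )
    expr = io_formats.read_expression_matrix(bundle / "expression.tsv")
    return ref_ppis, omap, dag, annotations, tables, expr


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full build and write every export.

    Outputs under ``config.output_dir``: scored edge table (TSV), node
    annotation table, SIF and GraphML network exports, guilt-by-association
    predictions for unannotated proteins, and a JSON run report with the
    tier / score / species-support / node-class histograms.  Any stage
    failure aborts the run and removes partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_stages(config, outdir)
    except Exception:
        logger.exception("pipeline aborted; removing partial outputs in %s", outdir)
        for p in outdir.glob("*"):
            if p.is_file():
                p.unlink()
        raise


def _run_stages(config: PipelineConfig, outdir: Path) -> RunReport:
    logger.info("stage read: loading bundle %s", config.bundle_dir)
    ref_ppis, omap, dag, annotations, tables, expr = _load_bundle(config)
    logger.info("stage read: %d reference PPIs, %d ortholog entries", len(ref_ppis), len(omap))

    name, kept = filter_by_miscore(ref_ppis, config.mi_threshold)
    logger.info("stage filter (%s): %d of %d reference PPIs kept", name, len(kept), len(ref_ppis))

    predictions = map_interologs(kept, omap)
    logger.info("stage map: %d canonical predicted pairs", len(predictions))

    n_overlap = n_added = 0
    if config.curated_pairs:
        predictions, n_overlap, n_added = integrate_curated(predictions, config.curated_pairs)
        logger.info("stage integrate: %d overlap, %d added", n_overlap, n_added)

    scores = score_all(
        predictions.values(), annotations, dag, omap, tables, expr, config.scoring
    )
    tiers = tier_counts(scores.values())
    logger.info("stage score: tiers %s", tiers)

    network = build_network(predictions.values())
    summary = network_summary(network)
    logger.info(
        "stage network: %d proteins, largest component %d",
        summary.n_proteins, summary.largest_component_size,
    )

    annotated = annotations.proteins()
    unannotated = sorted(network.nodes - annotated)
    gba_rows = []
    n_predicted = 0
    for protein in unannotated:
        pred = predict_functions(
            protein, network, annotations, dag, top_k=config.top_k
        )
        if pred.terms:
            n_predicted += 1
        for rank, (term, p_val) in enumerate(pred.terms, start=1):
            gba_rows.append(
                {"protein": protein, "rank": rank, "term": term,
                 "name": dag.name(term), "p_value": p_val}
            )
    logger.info("stage annotate: %d/%d unannotated proteins received terms",
                n_predicted, len(unannotated))

    # exports
    edge_records = []
    for i, pair in enumerate(sorted(predictions)):
        pred, sc = predictions[pair], scores[pair]
        edge_records.append({
            "pair_id": f"PAIR{i + 1:06d}",
            "protein_a": pair[0],
            "protein_b": pair[1],
            "origin": pred.origin,
            "s_species": sc.s_species,
            "s_coevo": sc.s_coevo,
            "s_go": sc.s_go,
            "s_ddi": sc.s_ddi,
            "s_loc": sc.s_loc,
            "cs": "" if sc.cs is None else round(sc.cs, 6),
            "s_coexp": sc.s_coexp,
            "total": sc.total,
            "tier": sc.tier,
        })
    io_formats.export_network(network, "TSV", outdir / "edges.tsv", edge_records)
    io_formats.export_network(network, "SIF", outdir / "network.sif")
    io_formats.export_network(network, "GraphML", outdir / "network.graphml")
    with (outdir / "nodes.tsv").open("w") as fh:
        fh.write("protein\tdegree\tnode_class\tannotated\n")
        from .network import degree_class
        for node in sorted(network.nodes):
            deg = network.degree(node)
            fh.write(f"{node}\t{deg}\t{degree_class(deg)}\t{int(node in annotated)}\n")
    with (outdir / "predicted_functions.tsv").open("w") as fh:
        fh.write("protein\trank\tterm\tname\tp_value\n")
        for row in gba_rows:
            fh.write(f"{row['protein']}\t{row['rank']}\t{row['term']}\t"
                     f"{row['name']}\t{row['p_value']:.6g}\n")

    score_hist: dict[str, int] = {}
    for sc in scores.values():
        key = f"{sc.total:g}"
        score_hist[key] = score_hist.get(key, 0) + 1
    n_self = sum(1 for p in predictions.values() if p.is_self)
    report = RunReport(
        n_total=len(predictions),
        n_self=n_self,
        n_hetero=len(predictions) - n_self,
        n_curated_overlap=n_overlap,
        n_curated_added=n_added,
        tier_counts=tiers,
        score_histogram=dict(sorted(score_hist.items(), key=lambda kv: float(kv[0]))),
        species_support_histogram=species_support_histogram(predictions.values()),
        node_class_histogram=class_histogram(network),
        n_proteins=summary.n_proteins,
        largest_component_size=summary.largest_component_size,
        average_partners=summary.average_partners,
        n_unannotated=len(unannotated),
        n_unannotated_predicted=n_predicted,
    )
    with (outdir / "report.json").open("w") as fh:
        json.dump(asdict(report), fh, indent=2, sort_keys=True)
    return report
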