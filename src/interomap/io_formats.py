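"""Readers and writers for every standard format the pipeline touches.

Inputs: PSI-MI TAB 2.5/2.7 reference interactomes, INPARANOID-style ortholog
TSVs, OBO 1.2 ontologies, GAF 2.x annotations, Pfam domain / DDI /
localization TSVs and gene x sample expression matrices.  Outputs: SIF,
GraphML and TSV edge/node tables replacing an interactive network viewer.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import obonet
import pandas as pd

from .types import (
    COMPARTMENTS,
    LOCALIZATION_EVIDENCE_CODES,
    NON_MATCHING_COMPARTMENTS,
    AnnotationSet,
    EvidenceTables,
    ExpressionMatrix,
    GODag,
    InteractomeNetwork,
    OrthologMap,
    ReferenceInteraction,
)

logger = logging.getLogger(__name__)

_NS_LONG_TO_CODE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


class FormatError(ValueError):
    """A file violates its declared format."""


def _first_accession(field: str) -> str:
    """Extract a protein accession from a MITAB identifier column.

    Prefers the first ``uniprotkb:`` token; falls back to the first token of
    any namespace (IntAct files mix namespaces).
    """
    tokens = field.split("|")
    for tok in tokens:
        if tok.startswith("uniprotkb:"):
            return tok.split(":", 1)[1].split("(")[0]
    first = tokens[0]
    return first.split(":", 1)[1].split("(")[0] if ":" in first else first


def read_mitab(path: str | Path, species: str) -> list[ReferenceInteraction]:
    """Read a PSI-MI TAB 2.5/2.7 file into reference interactions.

    The MI-score is parsed from the first ``intact-miscore:<float>`` token of
    the confidence column (column 15) and left missing when absent or
    unparsable.  No deduplication happens at this stage.
    """
    path = Path(path)
    records: list[ReferenceInteraction] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0].startswith("ID(") or cols[0].lower().startswith("id interactor"):
                continue  # header
            if len(cols) < 15:
                raise FormatError(f"{path}:{lineno}: expected >=15 MITAB columns, got {len(cols)}")
            id_a = _first_accession(cols[0])
            id_b = _first_accession(cols[1])
            mi_score: Optional[float] = None
            for tok in cols[14].split("|"):
                if tok.startswith("intact-miscore:"):
                    try:
                        mi_score = float(tok.split(":", 1)[1])
                    except ValueError:
                        logger.warning("%s:%d: unparsable miscore token %r", path, lineno, tok)
                        mi_score = None
                    break
            records.append(
                ReferenceInteraction(
                    species=species,
                    id_a=id_a,
                    id_b=id_b,
                    mi_score=mi_score,
                    detection_method=cols[6] if len(cols) > 6 else "-",
                    interaction_type=cols[11] if len(cols) > 11 else "-",
                    source_line=lineno,
                )
            )
    return records


def write_mitab(path: str | Path, records: Sequence[ReferenceInteraction]) -> Path:
    """Write minimal 15-column MITAB 2.5 lines (round-trips read_mitab)."""
    path = Path(path)
    header = [
        "#ID(s) interactor A", "ID(s) interactor B", "Alt. ID(s) A", "Alt. ID(s) B",
        "Alias(es) A", "Alias(es) B", "Interaction detection method(s)",
        "Publication 1st author(s)", "Publication Identifier(s)", "Taxid A",
        "Taxid B", "Interaction type(s)", "Source database(s)",
        "Interaction identifier(s)", "Confidence value(s)",
    ]
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            conf = f"intact-miscore:{r.mi_score}" if r.mi_score is not None else "-"
            cols = [
                f"uniprotkb:{r.id_a}", f"uniprotkb:{r.id_b}", "-", "-", "-", "-",
                r.detection_method, "-", "-", "-", "-", r.interaction_type, "-", "-", conf,
            ]
            fh.write("\t".join(cols) + "\n")
    return path


def read_ortholog_map(path: str | Path, species: Sequence[str]) -> OrthologMap:
    """Read a flat ortholog TSV (species, reference_accession,
    target_accession, confidence) into an :class:`OrthologMap`.

    Duplicate triples collapse.  An INPARANOID ``sqltable`` converts onto this
    layout by pairing each non-seed member with its cluster's target-species
    seed and carrying the inparalog score as the confidence column.
    """
    known = set(species)
    omap = OrthologMap()
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sp = row["species"]
            if sp not in known:
                raise FormatError(f"unknown species label {sp!r} in ortholog map")
            try:
                conf = float(row["confidence"])
            except ValueError as exc:
                raise FormatError(f"bad confidence {row['confidence']!r}") from exc
            if not (0.0 < conf <= 1.0):
                raise FormatError(f"ortholog confidence {conf} outside (0, 1]")
            omap.add(sp, row["reference_accession"], row["target_accession"], conf)
    logger.info("ortholog map: %d entries across %d species", len(omap), len(omap.species))
    return omap


def write_ortholog_map(path: str | Path, omap: OrthologMap) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("species\treference_accession\ttarget_accession\tconfidence\n")
        for species, ref, target, conf in sorted(omap.entries):
            fh.write(f"{species}\t{ref}\t{target}\t{conf}\n")
    return path


def read_obo(path: str | Path, include_part_of: bool = False) -> GODag:
    """Read an OBO 1.2 ontology into a :class:`GODag`.

    is_a edges are always loaded; part_of only when requested.  Obsolete
    terms are dropped (obonet excludes them).  Raises on cycles or unknown
    namespaces.
    """
    graph = obonet.read_obo(str(path))
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str, str]] = []
    for term_id, data in graph.nodes(data=True):
        ns_long = data.get("namespace")
        if ns_long not in _NS_LONG_TO_CODE:
            raise FormatError(f"term {term_id} has unknown namespace {ns_long!r}")
        terms[term_id] = (data.get("name", term_id), _NS_LONG_TO_CODE[ns_long])
        for parent in data.get("is_a", []):
            edges.append((term_id, parent, "is_a"))
        for rel in data.get("relationship", []):
            parts = rel.split()
            if len(parts) == 2 and parts[0] == "part_of":
                edges.append((term_id, parts[1], "part_of"))
    try:
        return GODag(terms, edges, include_part_of=include_part_of)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_obo(path: str | Path, dag: GODag) -> Path:
    """Write a GODag back to minimal OBO 1.2 stanzas."""
    code_to_long = {v: k for k, v in _NS_LONG_TO_CODE.items()}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("format-version: 1.2\nontology: go\n\n")
        for term in sorted(dag.terms):
            name, ns = dag.terms[term]
            fh.write(f"[Term]\nid: {term}\nname: {name}\nnamespace: {code_to_long[ns]}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent} ! {dag.name(parent)}\n")
            fh.write("\n")
    return path


def read_gaf(path: str | Path, dag: GODag) -> AnnotationSet:
    """Read a GAF 2.x annotation file validated against a companion DAG.

    NOT-qualified records are dropped; records whose term is missing from
    the DAG are dropped with a warning.
    """
    records: list[tuple[str, str, str, str]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise FormatError(f"{path}:{lineno}: GAF line has {len(cols)} columns (<15)")
            qualifier, term, evidence, aspect = cols[3], cols[4], cols[6], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if term not in dag:
                logger.warning("%s:%d: term %s not in ontology, dropped", path, lineno, term)
                continue
            if aspect not in _GAF_ASPECT:
                raise FormatError(f"{path}:{lineno}: unknown GAF aspect {aspect!r}")
            records.append((cols[1], term, _GAF_ASPECT[aspect], evidence))
    return AnnotationSet(records, dag)


def write_gaf(path: str | Path, records: Iterable[tuple[str, str, str, str]],
              db: str = "interomap") -> Path:
    """Write (protein, term, namespace, evidence) records as GAF 2.2 lines."""
    aspect = {v: k for k, v in _GAF_ASPECT.items()}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein, term, ns, code in sorted(records):
            cols = [db, protein, protein, "enables", term, "REF:0000001", code, "",
                    aspect[ns], protein, "", "protein", "taxon:0000", "20160101", db, "", ""]
            fh.write("\t".join(cols) + "\n")
    return path


def read_evidence_tables(
    domains_path: str | Path,
    ddi_path: str | Path,
    localization_path: str | Path,
    compartments: Sequence[str] = COMPARTMENTS,
) -> EvidenceTables:
    """Read domain assignments, the DDI table and localization records.

    Curated localization rows survive only with an accepted evidence code
    (EXP, IDA, IEP, IMP, IC, IEA, RCA, ISS); predicted rows are always kept.
    DDI pairs are canonicalized to sorted order.
    """
    tables = EvidenceTables()
    vocabulary = set(compartments) | NON_MATCHING_COMPARTMENTS
    with Path(domains_path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            start, end = int(row["start"]), int(row["end"])
            if start > end:
                raise FormatError(f"domain row {row['protein_id']}/{row['pfam_acc']}: start > end")
            tables.domains.add(
                (row["protein_id"], row["pfam_acc"], start, end, float(row["evalue"]))
            )
    with Path(ddi_path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            a, b = sorted((row["pfam_a"], row["pfam_b"]))
            tables.ddis.add((a, b))
    n_dropped = 0
    with Path(localization_path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            comp = row["compartment"]
            if comp not in vocabulary:
                raise FormatError(f"compartment {comp!r} not in vocabulary")
            code, origin = row["evidence_code"], row["origin"]
            if origin == "curated" and code not in LOCALIZATION_EVIDENCE_CODES:
                n_dropped += 1
                continue
            tables.localizations.add((row["protein_id"], comp, code, origin))
    if n_dropped:
        logger.info("dropped %d curated localization rows with unaccepted evidence", n_dropped)
    tables.build_indexes()
    return tables


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV; empty cells are missing values."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            raise FormatError(f"non-numeric cell(s) in sample {col!r}: {bad.head(3).to_dict()}")
    return ExpressionMatrix(frame)


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix) -> Path:
    matrix.frame.to_csv(path, sep="\t", index_label="gene_id", na_rep="")
    return path


def export_network(
    network: InteractomeNetwork,
    fmt: str,
    path: str | Path,
    edge_records: Optional[Sequence[dict]] = None,
) -> Path:
    """Export the network as SIF, GraphML or a scored TSV edge table.

    ``edge_records`` (one dict per scored pair) is required for the TSV
    format, which carries pair id, accessions, per-component evidence
    scores, the total and the confidence tier.
    """
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "SIF":
        with path.open("w") as fh:
            for a, b in sorted(network.edges):
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "GRAPHML":
        nx.write_graphml(network.graph, path)
    elif fmt == "TSV":
        if edge_records is None:
            edge_records = [
                {"pair_id": f"PAIR{i + 1:06d}", "protein_a": a, "protein_b": b}
                for i, (a, b) in enumerate(sorted(network.edges))
            ]
        frame = pd.DataFrame(edge_records)
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r} (use SIF, GraphML or TSV)")
    return path


def read_sif(path: str | Path) -> InteractomeNetwork:
    g = nx.Graph()
    with Path(path).open() as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) == 3:
                g.add_edge(parts[0].strip(), parts[2].strip())
            elif len(parts) == 1 and parts[0].strip():
                g.add_node(parts[0].strip())
    return InteractomeNetwork(g)


def read_graphml(path: str | Path) -> InteractomeNetwork:
    return InteractomeNetwork(nx.read_graphml(path))
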