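"""Seeded synthetic input bundles with a known planted truth.

Emulates everything the pipeline consumes — per-species reference
interactomes (MITAB), ortholog tables, a three-namespace ontology with GAF
annotations, Pfam domain / DDI / localization tables and a gene x sample
expression matrix — so that every stage is testable offline.  Planted target
pairs are back-translated through the sampled ortholog tables into the
reference interactomes, which makes interolog recovery exact by
construction; evidence layers are drawn concordant with the planted truth at
configurable rates and at background rates elsewhere.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import io_formats
from .interolog import canonical_pair
from .types import (
    COMPARTMENTS,
    ExpressionMatrix,
    GODag,
    OrthologMap,
    ReferenceInteraction,
)

DEFAULT_SPECIES = ("arabidopsis", "worm", "fly", "human", "rice", "yeast")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions the generated bundle emulates."""

    n_target_proteins: int = 240
    n_species: int = 6
    edges_per_species: int = 40          # species-private noise edges
    ortholog_coverage: float = 0.8       # per species, fraction of targets with an ortholog
    planted_complex_count: int = 8
    planted_complex_size: int = 5
    n_extra_pairs: int = 40              # planted pairs outside complexes
    p_multi_species: float = 0.25        # chance a planted pair transfers from >1 species
    p_shared_go: float = 0.8             # P(shared GO term in a namespace | true pair)
    p_ddi: float = 0.7                   # P(DDI support | true pair)
    p_coloc: float = 0.7                 # P(co-localization | true pair)
    rho_true: float = 0.8                # expression concordance parameter for true pairs
    rho_null: float = 0.0                # ... for background genes
    n_samples: int = 96
    mi_alpha: float = 2.0                # MI-score ~ Beta(alpha, beta)
    mi_beta: float = 2.0
    inparalog_rate: float = 0.15         # chance of a 2nd reference ortholog per species
    missing_rate: float = 0.02           # expression missingness (background genes only)
    species: tuple[str, ...] = DEFAULT_SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ortholog_coverage", "p_multi_species", "p_shared_go",
                     "p_ddi", "p_coloc", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0 < self.n_species <= len(self.species)):
            raise ValueError("n_species must be in 1..len(species)")
        if min(self.n_target_proteins, self.planted_complex_count,
               self.planted_complex_size, self.n_samples) < 1:
            raise ValueError("counts must be positive")
        if abs(self.rho_true) > 1 or abs(self.rho_null) > 1:
            raise ValueError("|rho| must be <= 1")


@dataclass(frozen=True)
class PlantedPair:
    pair: tuple[str, str]
    species: frozenset[str]
    go_flags: tuple[bool, bool, bool]  # shared-term flag per namespace BP/MF/CC
    ddi_flag: bool
    coloc_flag: bool
    complex_id: Optional[int]


@dataclass
class TruthTable:
    pairs: list[PlantedPair] = field(default_factory=list)

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(p.pair for p in self.pairs)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("protein_a\tprotein_b\tspecies\tgo_bp\tgo_mf\tgo_cc\tddi\tcoloc\tcomplex\n")
            for p in sorted(self.pairs, key=lambda x: x.pair):
                fh.write(
                    f"{p.pair[0]}\t{p.pair[1]}\t{','.join(sorted(p.species))}\t"
                    f"{int(p.go_flags[0])}\t{int(p.go_flags[1])}\t{int(p.go_flags[2])}\t"
                    f"{int(p.ddi_flag)}\t{int(p.coloc_flag)}\t"
                    f"{'' if p.complex_id is None else p.complex_id}\n"
                )
        return path


def generate_powerlaw_network(n_nodes: int, m: int, seed: int) -> list[tuple[str, str]]:
    """Seeded preferential-attachment (Barabasi-Albert) edge list.

    Connected, no duplicate edges; node labels ``N0000..``.
    """
    if not (n_nodes > m >= 1):
        raise ValueError("need n_nodes > m >= 1")
    g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    return [(f"N{a:05d}", f"N{b:05d}") for a, b in g.edges]


def _plant_truth(config: FixtureConfig, rng: np.random.Generator,
                 proteins: Sequence[str]) -> TruthTable:
    species = list(config.species[: config.n_species])
    pool = list(proteins)
    rng.shuffle(pool)
    truth = TruthTable()
    seen: set[tuple[str, str]] = set()
    complexes: list[list[str]] = []
    idx = 0
    for _ in range(config.planted_complex_count):
        members = pool[idx: idx + config.planted_complex_size]
        idx += config.planted_complex_size
        if len(members) < 2:
            break
        complexes.append(members)
    pair_specs: list[tuple[tuple[str, str], Optional[int]]] = []
    for cid, members in enumerate(complexes):
        for a, b in itertools.combinations(members, 2):
            pair_specs.append((canonical_pair(a, b), cid))
    for _ in range(config.n_extra_pairs):
        a, b = rng.choice(proteins, size=2, replace=False)
        pair_specs.append((canonical_pair(str(a), str(b)), None))
    for pair, cid in pair_specs:
        if pair in seen:
            continue
        seen.add(pair)
        n_sp = 2 if (len(species) > 1 and rng.random() < config.p_multi_species) else 1
        sp = frozenset(rng.choice(species, size=n_sp, replace=False).tolist())
        truth.pairs.append(
            PlantedPair(
                pair=pair,
                species=sp,
                go_flags=tuple(bool(rng.random() < config.p_shared_go) for _ in range(3)),
                ddi_flag=bool(rng.random() < config.p_ddi),
                coloc_flag=bool(rng.random() < config.p_coloc),
                complex_id=cid,
            )
        )
    return truth


def _build_orthologs(config: FixtureConfig, rng: np.random.Generator,
                     proteins: Sequence[str], truth: TruthTable) -> OrthologMap:
    """Sample per-species ortholog tables covering every planted pair.

    Each reference accession maps to exactly one target (a target may carry
    an extra inparalog accession), which keeps back-translation exact.
    """
    species = list(config.species[: config.n_species])
    omap = OrthologMap()
    required: dict[str, set[str]] = {s: set() for s in species}
    for p in truth.pairs:
        for s in p.species:
            required[s].update(p.pair)
    for s in species:
        prefix = s[:3].upper()
        n_cov = int(round(config.ortholog_coverage * len(proteins)))
        covered = set(rng.choice(proteins, size=n_cov, replace=False).tolist())
        covered |= required[s]
        for i, target in enumerate(sorted(covered)):
            omap.add(s, f"{prefix}_{i:05d}", target, 1.0)
            if rng.random() < config.inparalog_rate:
                omap.add(s, f"{prefix}_IN{i:05d}", target, 0.8)
    return omap


def _primary_ref(omap: OrthologMap, species: str, target: str) -> str:
    refs = sorted(
        ref for (s, ref, t, _) in omap.entries if s == species and t == target
    )
    return refs[0]


def _build_reference_interactomes(
    config: FixtureConfig, rng: np.random.Generator,
    truth: TruthTable, omap: OrthologMap,
) -> dict[str, list[ReferenceInteraction]]:
    species = list(config.species[: config.n_species])
    # invert once: species -> target -> refs
    ref_index: dict[str, dict[str, list[str]]] = {s: {} for s in species}
    for s, ref, target, _ in omap.entries:
        ref_index[s].setdefault(target, []).append(ref)
    for s in species:
        for t in ref_index[s]:
            ref_index[s][t].sort()
    interactomes: dict[str, list[ReferenceInteraction]] = {s: [] for s in species}
    for p in sorted(truth.pairs, key=lambda x: x.pair):
        for s in sorted(p.species):
            ra = ref_index[s][p.pair[0]][0]
            rb = ref_index[s][p.pair[1]][0]
            mi = float(np.round(rng.beta(config.mi_alpha, config.mi_beta), 4))
            interactomes[s].append(
                ReferenceInteraction(
                    species=s, id_a=ra, id_b=rb, mi_score=mi,
                    detection_method="psi-mi:MI:0018(two hybrid)",
                    interaction_type="psi-mi:MI:0915(physical association)",
                )
            )
    # species-private noise among reference proteins with no orthologs: these
    # never back-map, so planted recovery stays exact
    for s in species:
        prefix = s[:3].upper()
        for i in range(config.edges_per_species):
            a = f"{prefix}_NOISE{2 * i:04d}"
            b = f"{prefix}_NOISE{2 * i + 1:04d}"
            mi = float(np.round(rng.beta(config.mi_alpha, config.mi_beta), 4))
            interactomes[s].append(
                ReferenceInteraction(
                    species=s, id_a=a, id_b=b, mi_score=mi,
                    detection_method="psi-mi:MI:0018(two hybrid)",
                    interaction_type="psi-mi:MI:0915(physical association)",
                )
            )
    return interactomes


def _build_ontology() -> GODag:
    """Small fixed three-namespace ontology: root -> 10 branches -> 3 leaves."""
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str, str]] = []
    for ns_idx, ns in enumerate(("BP", "MF", "CC")):
        root = f"GO:{ns_idx + 1}000000"
        terms[root] = (f"{ns} root", ns)
        for b in range(10):
            branch = f"GO:{ns_idx + 1}0{b + 1:02d}000"
            terms[branch] = (f"{ns} branch {b}", ns)
            edges.append((branch, root, "is_a"))
            for leaf in range(3):
                leaf_id = f"GO:{ns_idx + 1}0{b + 1:02d}00{leaf + 1}"
                terms[leaf_id] = (f"{ns} branch {b} leaf {leaf}", ns)
                edges.append((leaf_id, branch, "is_a"))
    return GODag(terms, edges)


def _branch_leaf(ns_idx: int, branch: int, leaf: int) -> str:
    return f"GO:{ns_idx + 1}0{branch + 1:02d}00{leaf + 1}"


def _build_annotations(
    config: FixtureConfig, rng: np.random.Generator,
    proteins: Sequence[str], truth: TruthTable, dag: GODag,
) -> list[tuple[str, str, str, str]]:
    """GAF records: complex modules share branch terms; background is random.

    A planted pair with the GO flag set in a namespace gets both members
    annotated to the same leaf term of its module branch, so the pair shares
    a term after propagation.
    """
    records: set[tuple[str, str, str, str]] = set()
    namespaces = ("BP", "MF", "CC")
    complex_branch = {
        cid: int(rng.integers(10)) for cid in range(config.planted_complex_count)
    }
    extra_branch: dict[tuple[str, str], int] = {}
    for p in truth.pairs:
        for ns_idx, ns in enumerate(namespaces):
            if not p.go_flags[ns_idx]:
                continue
            if p.complex_id is not None:
                branch = complex_branch[p.complex_id]
            else:
                branch = extra_branch.setdefault(p.pair, int(rng.integers(10)))
            leaf = _branch_leaf(ns_idx, branch, int(rng.integers(3)))
            for member in p.pair:
                records.add((member, leaf, ns, "IEA"))
    # background annotations: most proteins get one random leaf per namespace
    for protein in proteins:
        for ns_idx, ns in enumerate(namespaces):
            if rng.random() < 0.7:
                leaf = _branch_leaf(ns_idx, int(rng.integers(10)), int(rng.integers(3)))
                records.add((protein, leaf, ns, "IEA"))
    return sorted(records)


def _build_evidence_tables(
    config: FixtureConfig, rng: np.random.Generator,
    proteins: Sequence[str], truth: TruthTable,
) -> tuple[list[tuple], list[tuple[str, str]], list[tuple]]:
    n_pfam = 60
    pfams = [f"PF{i + 1:05d}" for i in range(n_pfam)]
    domains: dict[str, list[str]] = {}
    domain_rows: list[tuple] = []
    for protein in proteins:
        n_dom = 1 + int(rng.random() < 0.4)
        assigned = rng.choice(pfams, size=n_dom, replace=False).tolist()
        domains[protein] = assigned
        start = 1
        for pf in assigned:
            length = int(rng.integers(40, 200))
            domain_rows.append((protein, pf, start, start + length, 1e-10))
            start += length + 10
    ddis: set[tuple[str, str]] = set()
    for p in truth.pairs:
        if p.ddi_flag:
            da = domains[p.pair[0]][0]
            db = domains[p.pair[1]][0]
            ddis.add(tuple(sorted((da, db))))
    for _ in range(30):  # background DDI noise
        a, b = rng.choice(pfams, size=2, replace=False)
        ddis.add(tuple(sorted((str(a), str(b)))))

    comp_of: dict[str, str] = {}
    # co-localized planted pairs must agree on a compartment; chains of
    # flagged pairs can connect whole modules, so assign one compartment per
    # connected component of the flagged-pair graph
    coloc_graph = nx.Graph()
    for p in truth.pairs:
        if p.coloc_flag:
            coloc_graph.add_edge(*p.pair)
    for comp_nodes in nx.connected_components(coloc_graph):
        compartment = str(rng.choice(COMPARTMENTS))
        for protein in comp_nodes:
            comp_of[protein] = compartment
    codes = ("IDA", "IEA", "ISS", "EXP")
    loc_rows: list[tuple] = []
    for protein in proteins:
        comp = comp_of.get(protein, str(rng.choice(COMPARTMENTS)))
        origin = "curated" if rng.random() < 0.6 else "predicted"
        code = str(rng.choice(codes)) if origin == "curated" else "IEA"
        loc_rows.append((protein, comp, code, origin))
    return domain_rows, sorted(ddis), loc_rows


def expression_for_pairs(
    truth: TruthTable,
    genes: Sequence[str],
    n_samples: int,
    rho_true: float,
    rho_null: float,
    seed: int,
) -> ExpressionMatrix:
    """Expression matrix whose sign concordance encodes the planted truth.

    Genes linked by planted pairs are grouped (connected components of the
    truth graph); per sample each group draws a deviation sign and members
    follow it with probability q = (1 + sqrt(rho_true)) / 2, giving pairwise
    concordance (1 + rho_true) / 2.  Background genes lean toward a global
    per-sample direction with q0 = (1 + sqrt(rho_null)) / 2 (independent
    coins at rho_null = 0).  Magnitudes keep every value at least 0.5 away
    from the nominal center so the empirical sample mean never flips a sign.
    """
    if abs(rho_true) > 1 or abs(rho_null) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(p.pair for p in truth.pairs if p.pair[0] != p.pair[1])
    group_of: dict[str, int] = {}
    grouped: set[str] = set()
    gid = 0
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            for gene in comp:
                group_of[gene] = gid
                grouped.add(gene)
            gid += 1
    n_groups = gid
    q_true = (1.0 + math.sqrt(max(rho_true, 0.0))) / 2.0
    q_null = (1.0 + math.sqrt(max(rho_null, 0.0))) / 2.0
    center = 10.0
    values = np.empty((len(genes), n_samples))
    group_signs = rng.choice([-1.0, 1.0], size=(max(n_groups, 1), n_samples))
    for i, gene in enumerate(genes):
        if gene in grouped:
            base = group_signs[group_of[gene]]
            follow = rng.random(n_samples) < q_true
            signs = np.where(follow, base, -base)
        else:
            signs = np.where(rng.random(n_samples) < q_null, 1.0, -1.0)
        magnitude = 0.5 + np.abs(rng.normal(size=n_samples))
        values[i] = center + signs * magnitude
    frame = pd.DataFrame(
        values, index=list(genes),
        columns=[f"sample_{j + 1:03d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(frame)


@dataclass
class BundlePaths:
    directory: Path
    mitab: dict[str, Path]
    orthologs: Path
    obo: Path
    gaf: Path
    domains: Path
    ddi: Path
    localization: Path
    expression: Path
    truth: Path


def generate_bundle(config: FixtureConfig, outdir: str | Path) -> tuple[BundlePaths, TruthTable]:
    """Write a complete seeded input bundle; returns its paths and the truth.

    Identical configs (including the seed) produce byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    proteins = [f"TP{i + 1:05d}" for i in range(config.n_target_proteins)]

    truth = _plant_truth(config, rng, proteins)
    omap = _build_orthologs(config, rng, proteins, truth)
    interactomes = _build_reference_interactomes(config, rng, truth, omap)
    dag = _build_ontology()
    gaf_records = _build_annotations(config, rng, proteins, truth, dag)
    domain_rows, ddi_rows, loc_rows = _build_evidence_tables(config, rng, proteins, truth)
    expr = expression_for_pairs(
        truth, proteins, config.n_samples, config.rho_true, config.rho_null,
        seed=int(rng.integers(2**31 - 1)),
    )
    if config.missing_rate > 0:
        planted = {g for p in truth.pairs for g in p.pair}
        mask_rows = [i for i, g in enumerate(proteins) if g not in planted]
        blank = rng.random((len(mask_rows), config.n_samples)) < config.missing_rate
        arr = expr.frame.to_numpy()
        for j, i in enumerate(mask_rows):
            arr[i, blank[j]] = np.nan
        expr = ExpressionMatrix(pd.DataFrame(arr, index=expr.genes, columns=expr.samples))

    mitab_paths: dict[str, Path] = {}
    for s in sorted(interactomes):
        mitab_paths[s] = io_formats.write_mitab(outdir / f"refppi_{s}.tsv", interactomes[s])
    paths = BundlePaths(
        directory=outdir,
        mitab=mitab_paths,
        orthologs=io_formats.write_ortholog_map(outdir / "orthologs.tsv", omap),
        obo=io_formats.write_obo(outdir / "ontology.obo", dag),
        gaf=io_formats.write_gaf(outdir / "annotations.gaf", gaf_records),
        domains=outdir / "domains.tsv",
        ddi=outdir / "ddi.tsv",
        localization=outdir / "localization.tsv",
        expression=io_formats.write_expression_matrix(outdir / "expression.tsv", expr),
        truth=truth.write(outdir / "truth.tsv"),
    )
    with paths.domains.open("w") as fh:
        fh.write("protein_id\tpfam_acc\tstart\tend\tevalue\n")
        for row in sorted(domain_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    with paths.ddi.open("w") as fh:
        fh.write("pfam_a\tpfam_b\tsource\n")
        for a, b in ddi_rows:
            fh.write(f"{a}\t{b}\tsynthetic\n")
    with paths.localization.open("w") as fh:
        fh.write("protein_id\tcompartment\tevidence_code\torigin\n")
        for row in sorted(loc_rows):
            fh.write("\t".join(row) + "\n")
    return paths, truth
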