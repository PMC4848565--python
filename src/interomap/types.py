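"""Domain types shared by every stage of the interactome pipeline.

All other modules consume and produce these containers; readers in
:mod:`interomap.io_formats` are the only place raw files are touched.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

NAMESPACES = ("BP", "MF", "CC")

#: GO evidence codes accepted for curated subcellular-localization records.
LOCALIZATION_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IEP", "IMP", "IC", "IEA", "RCA", "ISS"}
)

#: The 13 subcellular compartments used for co-localization scoring.
COMPARTMENTS = (
    "apoplast",
    "cell wall",
    "chloroplast",
    "cytoplasm",
    "cytoskeleton",
    "endoplasmic reticulum",
    "Golgi",
    "membrane",
    "mitochondria",
    "nucleus",
    "ribosome",
    "secreted",
    "vacuole",
)

#: Compartments that never support a co-localization match.
NON_MATCHING_COMPARTMENTS = frozenset({"undefined", "unknown"})

#: Adjacent / trafficking compartment groups: sharing any location within a
#: group scores the co-localization point even without an exact match.
DEFAULT_COMPARTMENT_GROUPS = (
    frozenset({"Golgi", "endoplasmic reticulum"}),
    frozenset({"Golgi", "vacuole"}),
    frozenset({"nucleus", "cytoplasm"}),
    frozenset({"cytoplasm", "membrane"}),
)


@dataclass(frozen=True)
class ReferenceInteraction:
    """One curated PPI in a reference species, with its MI-score."""

    species: str
    id_a: str
    id_b: str
    mi_score: Optional[float] = None
    detection_method: str = "-"
    interaction_type: str = "-"
    source_line: int = 0

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor accessions must be non-empty")
        if self.mi_score is not None and not (0.0 <= self.mi_score <= 1.0):
            raise ValueError(f"mi_score {self.mi_score!r} outside [0, 1]")


class OrthologMap:
    """Reference-protein -> target-protein correspondences per species.

    Entries are (species, reference_accession, target_accession, confidence)
    with duplicates on the (species, ref, target) triple collapsed.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str, float]] = ()):
        self._entries: dict[tuple[str, str, str], float] = {}
        # species -> ref accession -> set of target accessions
        self._forward: dict[str, dict[str, set[str]]] = {}
        # target accession -> set of species with >=1 ortholog
        self._species_of: dict[str, set[str]] = {}
        for species, ref, target, conf in entries:
            self.add(species, ref, target, conf)

    def add(self, species: str, ref: str, target: str, confidence: float = 1.0) -> None:
        if not (0.0 < confidence <= 1.0):
            raise ValueError(f"ortholog confidence {confidence!r} outside (0, 1]")
        self._entries[(species, ref, target)] = confidence
        self._forward.setdefault(species, {}).setdefault(ref, set()).add(target)
        self._species_of.setdefault(target, set()).add(species)

    def targets_of(self, species: str, ref: str) -> frozenset[str]:
        return frozenset(self._forward.get(species, {}).get(ref, ()))

    def species_with_ortholog(self, target: str) -> frozenset[str]:
        return frozenset(self._species_of.get(target, ()))

    @property
    def entries(self) -> frozenset[tuple[str, str, str, float]]:
        return frozenset((s, r, t, c) for (s, r, t), c in self._entries.items())

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._forward)

    def per_species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for (species, _, _) in self._entries:
            counts[species] = counts.get(species, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self._entries)


_NS_LONG = {"biological_process": "BP", "molecular_function": "MF", "cellular_component": "CC"}


class GODag:
    """Acyclic GO term graph restricted to is_a (optionally part_of) edges.

    Obsolete terms are excluded; each namespace has a single root term.
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str]],
        parent_edges: Iterable[tuple[str, str, str]],
        include_part_of: bool = False,
    ):
        #: term_id -> (name, namespace code)
        self.terms: dict[str, tuple[str, str]] = dict(terms)
        relations = {"is_a"} | ({"part_of"} if include_part_of else set())
        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent, rel in parent_edges:
            if rel not in relations:
                continue
            if child not in self.terms or parent not in self.terms:
                continue
            self._parents[child].add(parent)
        self._check_acyclic()
        self.roots: dict[str, str] = {}
        for term, (_, ns) in self.terms.items():
            if not self._parents[term]:
                if ns in self.roots and self.roots[ns] != term:
                    raise ValueError(f"multiple roots in namespace {ns}")
                self.roots[ns] = term
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parents in self._parents.items():
            for p in parents:
                self._children[p].add(child)

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self._parents.items():
            g.add_edges_from((child, p) for p in parents)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")

    def namespace(self, term: str) -> str:
        return self.terms[term][1]

    def name(self, term: str) -> str:
        return self.terms[term][0]

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._parents[term])

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._children[term])

    def ancestors(self, term: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable by repeatedly following parent edges."""
        if term not in self._ancestor_cache:
            anc: set[str] = set()
            stack = list(self._parents[term])
            while stack:
                t = stack.pop()
                if t not in anc:
                    anc.add(t)
                    stack.extend(self._parents[t])
            self._ancestor_cache[term] = frozenset(anc)
        anc = self._ancestor_cache[term]
        return anc | {term} if include_self else anc

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


class AnnotationSet:
    """Protein -> GO term assignments, indexed per namespace."""

    def __init__(self, records: Iterable[tuple[str, str, str, str]], dag: GODag):
        self.dag = dag
        self.records: set[tuple[str, str, str, str]] = set()
        self._by_protein: dict[str, dict[str, set[str]]] = {}
        for protein, term, ns, code in records:
            if term not in dag:
                raise ValueError(f"term {term} not in companion ontology")
            if dag.namespace(term) != ns:
                raise ValueError(f"namespace mismatch for {term}: {ns}")
            self.records.add((protein, term, ns, code))
            self._by_protein.setdefault(protein, {}).setdefault(ns, set()).add(term)

    def terms_of(self, protein: str, namespace: str) -> frozenset[str]:
        return frozenset(self._by_protein.get(protein, {}).get(namespace, ()))

    def propagated_terms(
        self, protein: str, namespace: str, exclude_root: bool = True
    ) -> frozenset[str]:
        """Direct terms plus all is_a ancestors, optionally minus the root."""
        out: set[str] = set()
        for t in self.terms_of(protein, namespace):
            out |= self.dag.ancestors(t, include_self=True)
        if exclude_root:
            out.discard(self.dag.roots.get(namespace, ""))
        return frozenset(out)

    def proteins(self, namespace: Optional[str] = None) -> frozenset[str]:
        if namespace is None:
            return frozenset(self._by_protein)
        return frozenset(
            p for p, by_ns in self._by_protein.items() if by_ns.get(namespace)
        )

    def __len__(self) -> int:
        return len(self.records)


class ExpressionMatrix:
    """Gene x sample expression values with missing-value support."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")
        if frame.shape[1] < 1:
            raise ValueError("expression matrix needs at least one sample")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def row(self, gene: str) -> np.ndarray:
        """Values for one gene; all-NaN if the gene is absent."""
        if gene in self.frame.index:
            return self.frame.loc[gene].to_numpy(dtype=float)
        return np.full(self.n_samples, np.nan)

    def sample_means(self) -> np.ndarray:
        """Per-sample mean over all measured genes."""
        return self.frame.mean(axis=0, skipna=True).to_numpy(dtype=float)


@dataclass
class EvidenceTables:
    """Pfam domain assignments, domain-domain interactions and localizations."""

    #: rows (protein_id, pfam_acc, start, end, evalue)
    domains: set[tuple[str, str, int, int, float]] = field(default_factory=set)
    #: canonical (sorted) Pfam pairs known/predicted to interact
    ddis: set[tuple[str, str]] = field(default_factory=set)
    #: rows (protein_id, compartment, evidence_code, origin)
    localizations: set[tuple[str, str, str, str]] = field(default_factory=set)

    def domains_of(self, protein: str) -> frozenset[str]:
        return frozenset(pf for p, pf, *_ in self.domains if p == protein)

    def compartments_of(self, protein: str) -> frozenset[str]:
        return frozenset(c for p, c, *_ in self.localizations if p == protein)

    def build_indexes(self) -> None:
        """Precompute per-protein lookups (idempotent; cheap convenience)."""
        dom: dict[str, set[str]] = {}
        for p, pf, *_ in self.domains:
            dom.setdefault(p, set()).add(pf)
        loc: dict[str, set[str]] = {}
        for p, c, *_ in self.localizations:
            loc.setdefault(p, set()).add(c)
        self._dom_idx = dom
        self._loc_idx = loc
        self.domains_of = lambda protein: frozenset(dom.get(protein, ()))  # type: ignore
        self.compartments_of = lambda protein: frozenset(loc.get(protein, ()))  # type: ignore


@dataclass
class PredictedInteraction:
    """A canonical target-proteome pair with its cross-species provenance."""

    pair: tuple[str, str]
    supporting_species: set[str] = field(default_factory=set)
    source_refs: set[tuple[str, str, str, Optional[float]]] = field(default_factory=set)
    origin: str = "predicted"  # predicted | curated | both

    def __post_init__(self) -> None:
        a, b = self.pair
        if self.pair != tuple(sorted((a, b))):
            raise ValueError("pair must be canonical (lexicographically sorted)")
        if self.origin in ("predicted", "both") and not self.supporting_species:
            raise ValueError("predicted pairs need non-empty supporting species")

    @property
    def is_self(self) -> bool:
        return self.pair[0] == self.pair[1]


@dataclass
class EvidenceScores:
    """Per-component evidence for one predicted pair plus total and tier."""

    s_species: int
    s_go: int
    s_ddi: int
    s_loc: int
    s_coexp: int
    s_coevo: int = 0
    cs: Optional[float] = None
    total: float = 0.0
    tier: str = "low"


@dataclass
class DatasetStats:
    """Confidence summary of one MI-score-filtered prediction set."""

    name: str
    n_total: int
    n_high: int
    frequency: Optional[float]
    enrichment_p: Optional[float]
    species_support_histogram: dict[int, int] = field(default_factory=dict)


class InteractomeNetwork:
    """Undirected predicted network (self-loops allowed).

    Degree follows the neighbor-count convention: a self-loop contributes
    one to its node, and parallel evidence never duplicates an edge.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        # nx neighbors() yields a self-loop partner once, as required
        return len(list(self.graph.neighbors(node)))

    def degrees(self) -> dict[str, int]:
        return {n: self.degree(n) for n in self.graph.nodes}

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self.graph.neighbors(node))

    def components(self) -> list[frozenset[str]]:
        return [frozenset(c) for c in nx.connected_components(self.graph)]


@dataclass
class TermPrediction:
    """Ranked guilt-by-association GO term assignments for one protein."""

    protein_id: str
    terms: list[tuple[str, float]] = field(default_factory=list)  # (term, p), p ascending

    def __post_init__(self) -> None:
        ps = [p for _, p in self.terms]
        if any(ps[i] > ps[i + 1] for i in range(len(ps) - 1)):
            raise ValueError("p-values must be non-decreasing down the ranking")


@dataclass
class ICTable:
    """Information content per term (nats), per namespace corpus."""

    ic: dict[str, float]
    counts: dict[str, int]
    corpus_size: dict[str, int]  # namespace -> root propagated count

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]
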