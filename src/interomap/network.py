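"""Topology of the predicted interactome.

Builds the undirected network, classifies nodes by partner count (free ends,
pipes and hubs of growing size), summarizes connectivity the way interactome
surveys tabulate it, and fits the log-log degree distribution to check the
scale-free pattern.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy import stats

from .types import AnnotationSet, GODag, InteractomeNetwork, PredictedInteraction

#: (label, lowest degree, highest degree); only the 10-100 small-hub band is
#: conventional — the other cutpoints are defaults and shift as networks grow.
DEFAULT_CLASS_BOUNDARIES: tuple[tuple[str, int, float], ...] = (
    ("free_end", 1, 1),
    ("pipe", 2, 2),
    ("minor_hub", 3, 9),
    ("small_hub", 10, 100),
    ("medium_hub", 101, 500),
    ("major_hub", 501, 1000),
    ("super_hub", 1001, math.inf),
)


@dataclass
class NetworkSummary:
    n_proteins: int
    n_interactions: int
    average_partners: int
    largest_component_size: int
    class_histogram: dict[str, int] = field(default_factory=dict)


@dataclass
class DegreeFit:
    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]] = field(default_factory=list)  # (log10 k, log10 P)


def build_network(
    predictions: Iterable[Union[PredictedInteraction, tuple[str, str]]]
) -> InteractomeNetwork:
    """Build the undirected network from canonical pairs (self-loops kept)."""
    g = nx.Graph()
    for p in predictions:
        a, b = p.pair if isinstance(p, PredictedInteraction) else p
        g.add_edge(a, b)
    return InteractomeNetwork(g)


def degree_class(
    degree: int,
    boundaries: Sequence[tuple[str, int, float]] = DEFAULT_CLASS_BOUNDARIES,
) -> str:
    """Node class label for a partner count (classes tile degrees >= 1)."""
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    for label, lo, hi in boundaries:
        if lo <= degree <= hi:
            return label
    raise ValueError(f"degree {degree} not covered by class boundaries")


def class_histogram(
    network: InteractomeNetwork,
    boundaries: Sequence[tuple[str, int, float]] = DEFAULT_CLASS_BOUNDARIES,
) -> dict[str, int]:
    hist = {label: 0 for label, _, _ in boundaries}
    for _, deg in network.degrees().items():
        hist[degree_class(deg, boundaries)] += 1
    return hist


def average_partners(n_interactions: int, n_proteins: int) -> int:
    """Average interacting partners: interactions / proteins, rounded half-up.

    This is the convention interactome comparison tables use, not the mean
    graph degree 2E/N.
    """
    if n_proteins <= 0:
        raise ValueError("need a positive protein count")
    return int(math.floor(n_interactions / n_proteins + 0.5))


def network_summary(
    network: InteractomeNetwork,
    boundaries: Sequence[tuple[str, int, float]] = DEFAULT_CLASS_BOUNDARIES,
) -> NetworkSummary:
    if network.n_nodes == 0:
        raise ValueError("cannot summarize an empty network")
    return NetworkSummary(
        n_proteins=network.n_nodes,
        n_interactions=network.n_edges,
        average_partners=average_partners(network.n_edges, network.n_nodes),
        largest_component_size=max(len(c) for c in network.components()),
        class_histogram=class_histogram(network, boundaries),
    )


def degree_distribution_fit(
    network_or_degrees: Union[InteractomeNetwork, Sequence[int]],
    n_bins: Optional[int] = 12,
) -> DegreeFit:
    """Least-squares line on (log10 k, log10 P(k)) over log degree bins.

    With ``n_bins=None`` each distinct degree contributes one point
    (P(k) = fraction of nodes with degree k).  With binning, P within a bin
    is the mean of P(k) over the distinct degrees present and k is their
    geometric mean — the standard log-binning that preserves a power law's
    slope.  Requires at least 3 distinct degrees.
    """
    if isinstance(network_or_degrees, InteractomeNetwork):
        degrees = list(network_or_degrees.degrees().values())
    else:
        degrees = list(network_or_degrees)
    degrees = [d for d in degrees if d >= 1]
    values, counts = np.unique(np.asarray(degrees), return_counts=True)
    if len(values) < 3:
        raise ValueError("degree distribution fit needs >= 3 distinct degrees")
    total = counts.sum()
    pk = counts / total
    if n_bins is None:
        xs = np.log10(values.astype(float))
        ys = np.log10(pk)
    else:
        lo, hi = math.log10(values.min()), math.log10(values.max())
        edges = np.logspace(lo, hi, n_bins + 1)
        edges[-1] *= 1.0 + 1e-9  # right-closed last bin
        xs_list, ys_list = [], []
        idx = np.digitize(values, edges) - 1
        for b in range(n_bins):
            mask = idx == b
            if not mask.any():
                continue
            k_geo = float(np.exp(np.mean(np.log(values[mask].astype(float)))))
            xs_list.append(math.log10(k_geo))
            ys_list.append(math.log10(float(np.mean(pk[mask]))))
        xs, ys = np.asarray(xs_list), np.asarray(ys_list)
        if len(xs) < 3:
            raise ValueError("too few occupied bins for a fit")
    fit = stats.linregress(xs, ys)
    return DegreeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        points=list(zip(xs.tolist(), ys.tolist())),
    )


def class_go_profile(
    network: InteractomeNetwork,
    class_labels: Sequence[str],
    annotations: AnnotationSet,
    dag: GODag,
    slim_terms: Sequence[str],
    boundaries: Sequence[tuple[str, int, float]] = DEFAULT_CLASS_BOUNDARIES,
) -> dict[str, dict[str, float]]:
    """Per GO-slim term: fraction of class members annotated to it.

    Membership uses ancestor propagation, so a protein annotated to a child
    of a slim term counts toward that slim term.  Returns
    ``{namespace: {term: fraction}}`` over the union of the named classes
    (e.g. ``["major_hub", "super_hub"]`` for the large hubs).
    """
    wanted = set(class_labels)
    members = [
        n for n, deg in network.degrees().items()
        if degree_class(deg, boundaries) in wanted
    ]
    profile: dict[str, dict[str, float]] = {}
    if not members:
        import logging

        logging.getLogger(__name__).warning("empty node class(es) %s", sorted(wanted))
        return profile
    for term in slim_terms:
        ns = dag.namespace(term)
        hits = sum(
            1 for m in members
            if term in annotations.propagated_terms(m, ns, exclude_root=False)
        )
        profile.setdefault(ns, {})[term] = hits / len(members)
    return profile


def hetero_count(n_total: int, n_self: int) -> int:
    """Heterodimer count: total pairs minus self-interactions."""
    if n_self > n_total:
        raise ValueError("self count exceeds total")
    return n_total - n_self
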