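"""Six-component evidence scoring of predicted protein pairs.

Each canonical pair is scored by: (1) the number of reference species its
interolog was transferred from (1-6), (2) the number of species the two
proteins co-evolved in (0-6, recorded but weighted 0 by default), (3) shared
GO namespaces after ancestor propagation (0-3), (4) domain-domain interaction
support (0/1), (5) subcellular co-localization (0/1) and (6) a co-expression
point (0/1) from the sign-concordance score CS.  Under the default weights
the total lies in [1, 12]; pairs tier as high (>= 7), medium ([2, 7)) or low
(< 2).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import (
    DEFAULT_COMPARTMENT_GROUPS,
    NAMESPACES,
    NON_MATCHING_COMPARTMENTS,
    AnnotationSet,
    EvidenceScores,
    EvidenceTables,
    ExpressionMatrix,
    GODag,
    OrthologMap,
    PredictedInteraction,
)


@dataclass(frozen=True)
class CoexpressionResult:
    """Per-sample concordance indicators and their average CS."""

    gamma: tuple[int, ...]
    cs: Optional[float]
    n_used: int


@dataclass
class ScoringConfig:
    """Weights, thresholds and compartment groups for evidence aggregation."""

    w_species: float = 1.0
    w_go: float = 1.0
    w_ddi: float = 1.0
    w_loc: float = 1.0
    w_coexp: float = 1.0
    w_coevo: float = 0.0  # recorded as metadata, not totalled by default
    tau: float = 0.5      # CS threshold converting co-expression to a point
    tier_high: float = 7.0
    tier_low: float = 2.0
    compartment_groups: tuple[frozenset[str], ...] = DEFAULT_COMPARTMENT_GROUPS

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        if self.tier_low >= self.tier_high:
            raise ValueError("tier cutoffs must be ordered low < high")


def shared_go_namespaces(
    a: str, b: str, annotations: AnnotationSet, dag: GODag
) -> int:
    """Number of GO namespaces (0-3) in which a and b share a term.

    Each protein's terms are propagated to all is_a ancestors, the namespace
    root excluded; a namespace scores when the propagated sets intersect.
    """
    score = 0
    for ns in NAMESPACES:
        if annotations.propagated_terms(a, ns) & annotations.propagated_terms(b, ns):
            score += 1
    return score


def coevolution_count(a: str, b: str, orthologs: OrthologMap) -> int:
    """Number of reference species in which both proteins have an ortholog."""
    return len(
        orthologs.species_with_ortholog(a) & orthologs.species_with_ortholog(b)
    )


def ddi_support(a: str, b: str, tables: EvidenceTables) -> int:
    """1 iff some Pfam domain of a and some domain of b form a known DDI.

    Order-insensitive; homotypic pairs (same domain on both sides) count.
    """
    doms_a, doms_b = tables.domains_of(a), tables.domains_of(b)
    for da in doms_a:
        for db in doms_b:
            if tuple(sorted((da, db))) in tables.ddis:
                return 1
    return 0


def colocalization(
    a: str,
    b: str,
    tables: EvidenceTables,
    groups: Sequence[frozenset[str]] = DEFAULT_COMPARTMENT_GROUPS,
) -> int:
    """1 iff the proteins share a compartment or sit in one adjacent group.

    ``undefined`` and ``unknown`` never match anything.
    """
    comps_a = tables.compartments_of(a) - NON_MATCHING_COMPARTMENTS
    comps_b = tables.compartments_of(b) - NON_MATCHING_COMPARTMENTS
    if comps_a & comps_b:
        return 1
    for group in groups:
        if comps_a & group and comps_b & group:
            return 1
    return 0


def coexpression_score(a: str, b: str, expr: ExpressionMatrix) -> CoexpressionResult:
    """Sign-concordance co-expression score CS for a pair of genes.

    In each sample i the deviations of the two genes from that sample's mean
    over all measured genes are compared: gamma_i = 1 when the deviations
    have the same strict sign, else 0 (missing values and exact-zero
    deviations score 0).  CS = sum(gamma) / N with N the total sample count,
    so unmeasured samples depress the score.  CS is missing only when
    neither gene was measured in any sample.
    """
    means = expr.sample_means()
    x1, x2 = expr.row(a), expr.row(b)
    if np.all(np.isnan(x1)) and np.all(np.isnan(x2)):
        return CoexpressionResult(gamma=(0,) * expr.n_samples, cs=None, n_used=0)
    d1, d2 = x1 - means, x2 - means
    prod = d1 * d2
    with np.errstate(invalid="ignore"):
        gamma = np.where(np.isnan(prod), 0, (prod > 0).astype(int))
    n_used = int(np.sum(~np.isnan(x1) & ~np.isnan(x2)))
    cs = float(gamma.sum()) / expr.n_samples
    return CoexpressionResult(gamma=tuple(int(g) for g in gamma), cs=cs, n_used=n_used)


def tier_of(total: float, config: ScoringConfig = ScoringConfig()) -> str:
    """Confidence tier: high (>= 7), medium ([2, 7)), low (< 2) by default."""
    if total >= config.tier_high:
        return "high"
    if total < config.tier_low:
        return "low"
    return "medium"


def aggregate_score(
    s_species: int,
    s_go: int,
    s_ddi: int,
    s_loc: int,
    cs: Optional[float],
    s_coevo: int = 0,
    config: ScoringConfig = ScoringConfig(),
) -> EvidenceScores:
    """Combine per-component evidence into a total score and tier.

    The co-expression point is 1 iff CS >= tau (missing CS scores 0).
    Co-evolution is recorded but enters the total only with a non-zero
    configured weight.
    """
    if not (1 <= s_species <= 6):
        raise ValueError(f"s_species {s_species} outside 1..6")
    if not (0 <= s_go <= 3):
        raise ValueError(f"s_go {s_go} outside 0..3")
    if s_ddi not in (0, 1) or s_loc not in (0, 1):
        raise ValueError("s_ddi and s_loc must be 0 or 1")
    if not (0 <= s_coevo <= 6):
        raise ValueError(f"s_coevo {s_coevo} outside 0..6")
    if cs is not None and not (0.0 <= cs <= 1.0):
        raise ValueError(f"cs {cs} outside [0, 1]")
    s_coexp = 1 if (cs is not None and cs >= config.tau) else 0
    total = (
        config.w_species * s_species
        + config.w_go * s_go
        + config.w_ddi * s_ddi
        + config.w_loc * s_loc
        + config.w_coexp * s_coexp
        + config.w_coevo * s_coevo
    )
    return EvidenceScores(
        s_species=s_species,
        s_go=s_go,
        s_ddi=s_ddi,
        s_loc=s_loc,
        s_coexp=s_coexp,
        s_coevo=s_coevo,
        cs=cs,
        total=total,
        tier=tier_of(total, config),
    )


def score_pair(
    pair: PredictedInteraction,
    annotations: AnnotationSet,
    dag: GODag,
    orthologs: OrthologMap,
    tables: EvidenceTables,
    expr: ExpressionMatrix,
    config: ScoringConfig = ScoringConfig(),
) -> EvidenceScores:
    """Compute all six components for one predicted pair and aggregate."""
    a, b = pair.pair
    result = coexpression_score(a, b, expr)
    return aggregate_score(
        s_species=max(1, len(pair.supporting_species)),
        s_go=shared_go_namespaces(a, b, annotations, dag),
        s_ddi=ddi_support(a, b, tables),
        s_loc=colocalization(a, b, tables, config.compartment_groups),
        cs=result.cs,
        s_coevo=coevolution_count(a, b, orthologs),
        config=config,
    )


def score_all(
    predictions: Iterable[PredictedInteraction],
    annotations: AnnotationSet,
    dag: GODag,
    orthologs: OrthologMap,
    tables: EvidenceTables,
    expr: ExpressionMatrix,
    config: ScoringConfig = ScoringConfig(),
) -> dict[tuple[str, str], EvidenceScores]:
    return {
        p.pair: score_pair(p, annotations, dag, orthologs, tables, expr, config)
        for p in predictions
    }


def tier_counts(scores: Iterable[EvidenceScores]) -> dict[str, int]:
    counts = {"high": 0, "medium": 0, "low": 0}
    for s in scores:
        counts[s.tier] += 1
    return counts


# --- dataset-level ratio statistics -----------------------------------------

def domain_density(n_domain_assignments: int, n_proteins: int) -> float:
    """Average number of Pfam domain assignments per protein."""
    if n_proteins <= 0:
        raise ValueError("need a positive protein count")
    return n_domain_assignments / n_proteins


def colocalized_fraction(n_colocalized: int, n_with_localization: int) -> float:
    """Fraction of localization-informative pairs that are co-localized."""
    if n_with_localization <= 0:
        raise ValueError("need a positive informative-pair count")
    return n_colocalized / n_with_localization


def expression_missing_fraction(n_missing: int, n_total: int) -> float:
    """Fraction of pairs with no expression information in any sample."""
    if n_total <= 0:
        raise ValueError("need a positive pair count")
    return n_missing / n_total
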