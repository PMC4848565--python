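"""Interolog transfer: map reference-species PPIs onto the target proteome.

A target pair (A, B) is predicted wherever some reference species holds a
curated interaction (x, y) with A orthologous to x and B orthologous to y.
Ortholog expansion is all-vs-all across ortholog-group members; predictions
reachable from several species merge, accumulating species support.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom

from .types import DatasetStats, OrthologMap, PredictedInteraction, ReferenceInteraction


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a protein pair lexicographically (idempotent dedup key)."""
    if not a or not b:
        raise ValueError("protein identifiers must be non-empty")
    return (a, b) if a <= b else (b, a)


def map_interologs(
    ref_ppis: Iterable[ReferenceInteraction], orthologs: OrthologMap
) -> dict[tuple[str, str], PredictedInteraction]:
    """Transfer reference interactions to the target proteome via orthologs.

    For each reference PPI (x, y) in species s, every combination (A, B)
    with A an ortholog of x and B an ortholog of y in s is emitted.  Pairs
    are canonicalized; duplicates merge with union species support and
    accumulated source references.  Self-interactions are retained.
    """
    predictions: dict[tuple[str, str], PredictedInteraction] = {}
    for ref in ref_ppis:
        targets_a = orthologs.targets_of(ref.species, ref.id_a)
        targets_b = orthologs.targets_of(ref.species, ref.id_b)
        if not targets_a or not targets_b:
            continue
        source = (ref.species, ref.id_a, ref.id_b, ref.mi_score)
        for ta in targets_a:
            for tb in targets_b:
                pair = canonical_pair(ta, tb)
                hit = predictions.get(pair)
                if hit is None:
                    predictions[pair] = PredictedInteraction(
                        pair=pair,
                        supporting_species={ref.species},
                        source_refs={source},
                    )
                else:
                    hit.supporting_species.add(ref.species)
                    hit.source_refs.add(source)
    return predictions


def filter_by_miscore(
    ref_ppis: Sequence[ReferenceInteraction], threshold: float
) -> tuple[str, list[ReferenceInteraction]]:
    """Keep reference PPIs with MI-score >= threshold.

    Records with a missing MI-score cannot be placed on the quality ladder
    and survive only the threshold-0 pass.  Returns the conventional
    ``High_quality_<threshold>`` dataset name alongside the subset.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"MI-score threshold {threshold} outside [0, 1]")
    if threshold == 0.0:
        kept = list(ref_ppis)
    else:
        kept = [r for r in ref_ppis if r.mi_score is not None and r.mi_score >= threshold]
    return f"High_quality_{threshold:g}", kept


def integrate_curated(
    predictions: dict[tuple[str, str], PredictedInteraction],
    curated_pairs: Iterable[tuple[str, str]],
) -> tuple[dict[tuple[str, str], PredictedInteraction], int, int]:
    """Merge experimentally curated pairs into the prediction set.

    Overlapping pairs switch origin to ``both``; curated-only pairs are
    added with empty species support.  Returns (merged, n_overlap, n_added).
    """
    merged = dict(predictions)
    n_overlap = n_added = 0
    for pair in set(map(lambda p: canonical_pair(*p), curated_pairs)):
        if pair in merged:
            merged[pair].origin = "both"
            n_overlap += 1
        else:
            merged[pair] = PredictedInteraction(pair=pair, origin="curated")
            n_added += 1
    return merged, n_overlap, n_added


def curated_overlap_fraction(n_overlap: int, n_curated: int) -> float:
    """Fraction of curated interactions recovered by the predictions."""
    if n_curated <= 0:
        raise ValueError("need a positive curated count")
    return n_overlap / n_curated


def species_support_histogram(
    predictions: Iterable[PredictedInteraction],
) -> dict[int, int]:
    """Histogram of |supporting species| over predicted pairs."""
    hist: dict[int, int] = {}
    for p in predictions:
        m = len(p.supporting_species)
        hist[m] = hist.get(m, 0) + 1
    return hist


def multi_species_fraction(histogram: dict[int, int]) -> float:
    """Fraction of pairs supported by more than one reference species."""
    total = sum(histogram.values())
    if total == 0:
        raise ValueError("empty histogram")
    return sum(c for m, c in histogram.items() if m >= 2) / total


def dataset_confidence_stats(
    name: str,
    n_total: int,
    n_high: int,
    population_total: Optional[int] = None,
    population_high: Optional[int] = None,
    histogram: Optional[dict[int, int]] = None,
) -> DatasetStats:
    """Confidence summary of one MI-filtered dataset.

    ``frequency`` is the high-confidence fraction n_high / n_total.  The
    enrichment p-value is the upper-tail hypergeometric probability of
    drawing >= n_high high-confidence interactions in a sample of n_total
    from a population of ``population_total`` containing ``population_high``.
    """
    if n_total == 0:
        return DatasetStats(name, 0, 0, None, None, histogram or {})
    if histogram is not None and sum(histogram.values()) != n_total:
        raise ValueError("species-support histogram does not sum to n_total")
    frequency = n_high / n_total
    enrichment_p: Optional[float] = None
    if population_total is not None and population_high is not None:
        enrichment_p = float(
            hypergeom.sf(n_high - 1, population_total, population_high, n_total)
        )
    return DatasetStats(name, n_total, n_high, frequency, enrichment_p, histogram or {})


def stats_for_scored_dataset(
    name: str,
    predictions: Sequence[PredictedInteraction],
    tiers: Sequence[str],
    population_total: Optional[int] = None,
    population_high: Optional[int] = None,
) -> DatasetStats:
    """Dataset statistics computed from scored predictions and their tiers."""
    if len(predictions) != len(tiers):
        raise ValueError("one tier per prediction required")
    n_high = sum(1 for t in tiers if t == "high")
    return dataset_confidence_stats(
        name,
        len(predictions),
        n_high,
        population_total,
        population_high,
        species_support_histogram(predictions),
    )
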