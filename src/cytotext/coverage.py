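"""Ontology coverage statistics.

Depth histograms are over unique term ids by default, matching "number of
terms present" semantics; a mention-frequency-weighted variant is available
via ``weighted=True`` with a multiset input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus_model import Ontology, ancestors, term_depth

logger = logging.getLogger(__name__)


@dataclass
class DepthStats:
    histogram: dict[int, int]
    mean_depth: float
    n_terms: int
    n_excluded: int = 0  # unresolved or unreachable ids


def depth_stats(term_ids: Iterable[str], ontology: Ontology,
                weighted: bool = False) -> DepthStats:
    """Histogram of term depths and their mean.

    Ids that do not resolve, or that are unreachable from the root, are
    logged and excluded (counted in ``n_excluded``).
    """
    counts: Counter[str] = Counter(term_ids)
    if not weighted:
        counts = Counter(set(counts))
    histogram: Counter[int] = Counter()
    excluded = 0
    for term_id, mult in counts.items():
        resolved = ontology.resolve(term_id)
        if resolved is None:
            logger.warning("unresolved id %s excluded from depth statistics", term_id)
            excluded += mult
            continue
        depth = term_depth(ontology, resolved)
        if depth is None:
            logger.warning("id %s unreachable from root; excluded", term_id)
            excluded += mult
            continue
        histogram[depth] += mult
    n = sum(histogram.values())
    mean = sum(d * c for d, c in histogram.items()) / n if n else 0.0
    return DepthStats(histogram=dict(sorted(histogram.items())),
                      mean_depth=mean, n_terms=n, n_excluded=excluded)


def depth_l1(stats_a: DepthStats, stats_b: DepthStats) -> float:
    """Sum of absolute differences between normalized depth distributions.

    Bounded by [0, 2]; 0 for identical shapes, 2 for disjoint supports.
    """
    if stats_a.n_terms == 0 or stats_b.n_terms == 0:
        raise ValueError("depth statistics must be nonempty")
    depths = set(stats_a.histogram) | set(stats_b.histogram)
    return sum(abs(stats_a.histogram.get(d, 0) / stats_a.n_terms
                   - stats_b.histogram.get(d, 0) / stats_b.n_terms)
               for d in depths)


def lineage_counts(term_ids: Iterable[str], ontology: Ontology,
                   lineage_map: Mapping[str, set[str]]) -> dict[str, int]:
    """Count terms per lineage.

    A term counts toward lineage L iff L's root set intersects the term's
    self-plus-ancestors set; terms under multiple lineage roots count in
    each (ancestors spanning multiple lineages are counted in all of them).
    """
    for lineage, roots in lineage_map.items():
        for root in roots:
            if root not in ontology:
                raise ValueError(f"lineage {lineage!r} root {root!r} not in ontology")
    counts = {lineage: 0 for lineage in lineage_map}
    for term_id in term_ids:
        resolved = ontology.resolve(term_id)
        if resolved is None:
            continue
        closure = ancestors(ontology, resolved) | {resolved}
        for lineage, roots in lineage_map.items():
            if roots & closure:
                counts[lineage] += 1
    return counts
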