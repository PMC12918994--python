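"""Train/validation/test partitioning by iterative hill climbing.

The objective balances annotation composition across subsets (entity-type
proportions, passage-length distribution, MeSH-cluster frequency — each as
L1 distance between per-subset normalized distributions and the corpus-wide
one) while rewarding identifiers and mentions that occur in exactly one
subset. Swap proposals never change subset sizes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corpus_model import AnnotatedCorpus
from .designed_sampler import DEFAULT_LENGTH_BINS, length_bin_label

SUBSETS = ("train", "valid", "test")
DEFAULT_RATIOS = (1.0 / 2.0, 1.0 / 6.0, 1.0 / 3.0)


@dataclass
class Split:
    assignment: list[str]  # per passage index, one of SUBSETS
    ratios: tuple[float, float, float] = DEFAULT_RATIOS

    def indices(self, subset: str) -> list[int]:
        return [i for i, s in enumerate(self.assignment) if s == subset]

    def sizes(self) -> dict[str, int]:
        c = Counter(self.assignment)
        return {s: c.get(s, 0) for s in SUBSETS}


def subset_sizes(n: int, ratios: tuple[float, float, float] = DEFAULT_RATIOS) -> dict[str, int]:
    """floor(ratio * N) per subset, remainder assigned to train."""
    sizes = {s: int(r * n) for s, r in zip(SUBSETS, ratios)}
    sizes["train"] += n - sum(sizes.values())
    return sizes


@dataclass
class SplitObjective:
    w_entity_type: float = 1.0
    w_length: float = 1.0
    w_clusters: float = 1.0
    w_unique_ids: float = 1.0
    w_unique_mentions: float = 1.0
    length_bins: tuple[int, ...] = DEFAULT_LENGTH_BINS

    def __post_init__(self) -> None:
        for w in (self.w_entity_type, self.w_length, self.w_clusters,
                  self.w_unique_ids, self.w_unique_mentions):
            if w < 0:
                raise ValueError("objective weights must be nonnegative")


def _l1_to_global(per_subset: dict[str, Counter], global_counts: Counter) -> float:
    g_total = sum(global_counts.values())
    if g_total == 0:
        return 0.0
    dev = 0.0
    for counts in per_subset.values():
        total = sum(counts.values())
        if total == 0:
            dev += 2.0  # maximally divergent empty subset
            continue
        for value, g in global_counts.items():
            dev += abs(counts.get(value, 0) / total - g / g_total)
    return dev


def score_split(corpus: AnnotatedCorpus, split: Split,
                objective: SplitObjective | None = None) -> float:
    """Deterministic objective value; lower is better."""
    objective = objective or SplitObjective()
    entity: dict[str, Counter] = {s: Counter() for s in SUBSETS}
    length: dict[str, Counter] = {s: Counter() for s in SUBSETS}
    clusters: dict[str, Counter] = {s: Counter() for s in SUBSETS}
    id_subsets: dict[str, set[str]] = {}
    mention_subsets: dict[str, set[str]] = {}
    g_entity: Counter = Counter()
    g_length: Counter = Counter()
    g_clusters: Counter = Counter()
    for i, passage in enumerate(corpus.passages):
        s = split.assignment[i]
        lb = length_bin_label(len(passage.text), objective.length_bins)
        length[s][lb] += 1
        g_length[lb] += 1
        for c in passage.mesh_clusters:
            clusters[s][c] += 1
            g_clusters[c] += 1
        for ann in passage.annotations:
            entity[s][ann.entity_type] += 1
            g_entity[ann.entity_type] += 1
            mention_subsets.setdefault(ann.span.text.casefold(), set()).add(s)
            for link in ann.links:
                id_subsets.setdefault(link.term_id, set()).add(s)
    unique_ids = sum(1 for subs in id_subsets.values() if len(subs) == 1)
    unique_mentions = sum(1 for subs in mention_subsets.values() if len(subs) == 1)
    return (objective.w_entity_type * _l1_to_global(entity, g_entity)
            + objective.w_length * _l1_to_global(length, g_length)
            + objective.w_clusters * _l1_to_global(clusters, g_clusters)
            - objective.w_unique_ids * unique_ids
            - objective.w_unique_mentions * unique_mentions)


def hill_climb_split(corpus: AnnotatedCorpus,
                     ratios: tuple[float, float, float] = DEFAULT_RATIOS,
                     objective: SplitObjective | None = None,
                     seed: int = 0,
                     max_stale: int = 500) -> Split:
    """Hill-climb from a seeded random partition at exact configured sizes.

    Repeatedly proposes swapping two passages across subsets (subsets drawn
    with probability proportional to size, passages uniformly) and accepts
    iff the score strictly decreases; stops after ``max_stale`` consecutive
    rejections. The accepted-score sequence is strictly decreasing and
    subset sizes never change.
    """
    n = len(corpus.passages)
    if n < 3:
        raise ValueError("need at least 3 passages to split")
    objective = objective or SplitObjective()
    rng = np.random.default_rng(seed)
    sizes = subset_sizes(n, ratios)
    assignment: list[str] = []
    for s in SUBSETS:
        assignment.extend([s] * sizes[s])
    perm = rng.permutation(n)
    assignment = [assignment[j] for j in np.argsort(perm)]
    split = Split(assignment=assignment, ratios=ratios)
    members: dict[str, list[int]] = {s: split.indices(s) for s in SUBSETS}
    current = score_split(corpus, split, objective)
    sub_p = np.array([sizes[s] for s in SUBSETS], dtype=float)
    sub_p /= sub_p.sum()
    stale = 0
    while stale < max_stale:
        s1, s2 = SUBSETS[int(rng.choice(3, p=sub_p))], SUBSETS[int(rng.choice(3, p=sub_p))]
        if s1 == s2 or not members[s1] or not members[s2]:
            stale += 1
            continue
        i1 = members[s1][int(rng.integers(len(members[s1])))]
        i2 = members[s2][int(rng.integers(len(members[s2])))]
        split.assignment[i1], split.assignment[i2] = s2, s1
        proposed = score_split(corpus, split, objective)
        if proposed < current:
            current = proposed
            members[s1].remove(i1)
            members[s2].remove(i2)
            members[s1].append(i2)
            members[s2].append(i1)
            stale = 0
        else:
            split.assignment[i1], split.assignment[i2] = s1, s2
            stale += 1
    return split
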