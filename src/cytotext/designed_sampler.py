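"""Designed passage sampling by greedy KL-divergence minimization.

A pool of passages is summarized per discrete feature type (year, journal,
passage type, length bin, tokens, MeSH clusters); a target distribution is
estimated from the pool, flattened with temperature scaling, multiplied by
configured adjustments, and passages are then greedily selected so that the
selected set's distribution tracks the adjusted target, under a per-article
cap.

Multi-valued feature types (tokens, clusters) contribute fractional mass
``1/len(values)`` per passage so every passage carries total mass 1 per
feature type. Per-feature-type KL terms are combined as a weighted sum
(default weight 1).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .corpus_model import Passage

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

FEATURE_TYPES = ("year", "journal", "passage_type", "length_bin", "tokens",
                 "mesh_clusters")

DEFAULT_LENGTH_BINS = (50, 100, 200, 400, 800, 1600)


class SamplerConfigError(ValueError):
    pass


# FeatureVector: feature_type -> {value: fractional mass}, masses sum to 1
# per feature type (empty dict when the passage has no values of that type).
FeatureVector = dict[str, dict[str, float]]


def tokenize(text: str) -> list[str]:
    """Maximal runs of letters/digits, case-folded."""
    return [m.group(0).casefold() for m in _TOKEN_RE.finditer(text)]


def length_bin_label(length: int, length_bins: Sequence[int]) -> str:
    edges = list(length_bins)
    prev = 0
    for edge in edges:
        if length < edge:
            return f"{prev}-{edge}"
        prev = edge
    return f"{edges[-1]}+"


def extract_features(passage: Passage,
                     length_bins: Sequence[int] = DEFAULT_LENGTH_BINS) -> FeatureVector:
    """Deterministic discrete feature summary of one passage."""
    if any(b >= c for b, c in zip(length_bins, length_bins[1:])):
        raise SamplerConfigError("length bin edges must be strictly increasing")
    tokens = sorted(set(tokenize(passage.text)))
    fv: FeatureVector = {
        "year": {str(passage.year): 1.0},
        "journal": {passage.journal: 1.0} if passage.journal else {},
        "passage_type": {passage.passage_type: 1.0},
        "length_bin": {length_bin_label(len(passage.text), length_bins): 1.0},
        "tokens": {t: 1.0 / len(tokens) for t in tokens} if tokens else {},
        "mesh_clusters": ({c: 1.0 / len(passage.mesh_clusters)
                           for c in sorted(passage.mesh_clusters)}
                          if passage.mesh_clusters else {}),
    }
    return fv


@dataclass
class FeatureDistribution:
    """Per-feature-type discrete probability tables."""

    probs: dict[str, dict[str, float]]
    epsilon: float = 1e-6

    def feature_types(self) -> list[str]:
        return list(self.probs)

    def check(self) -> None:
        for ft, table in self.probs.items():
            total = sum(table.values())
            if table and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{ft} probabilities sum to {total}")
            if any(p < 0 for p in table.values()):
                raise ValueError(f"{ft} has negative probability")


def empirical_distribution(pool: Iterable[FeatureVector],
                           epsilon: float = 1e-6,
                           vocab: Optional[dict[str, set[str]]] = None
                           ) -> FeatureDistribution:
    """Smoothed empirical distribution: (mass + eps) / (total + eps * |vocab|)."""
    pool = list(pool)
    if not pool:
        raise ValueError("empty feature pool")
    counts: dict[str, dict[str, float]] = {}
    for fv in pool:
        for ft, table in fv.items():
            bucket = counts.setdefault(ft, {})
            for value, mass in table.items():
                bucket[value] = bucket.get(value, 0.0) + mass
    probs: dict[str, dict[str, float]] = {}
    for ft, bucket in counts.items():
        values = set(bucket)
        if vocab and ft in vocab:
            values |= vocab[ft]
        total = sum(bucket.values()) + epsilon * len(values)
        probs[ft] = {v: (bucket.get(v, 0.0) + epsilon) / total for v in sorted(values)}
    return FeatureDistribution(probs=probs, epsilon=epsilon)


def temper(dist: FeatureDistribution, T: float) -> FeatureDistribution:
    """Temperature scaling: p <- p**(1/T), renormalized per feature type.

    T > 1 flattens toward uniform (emphasizing long-tail values); T = 1 is
    the identity.
    """
    if T <= 0:
        raise SamplerConfigError(f"temperature must be positive, got {T}")
    out: dict[str, dict[str, float]] = {}
    for ft, table in dist.probs.items():
        powered = {v: p ** (1.0 / T) for v, p in table.items()}
        z = sum(powered.values())
        out[ft] = {v: p / z for v, p in powered.items()} if z else {}
    return FeatureDistribution(probs=out, epsilon=dist.epsilon)


Adjustment = tuple[str, object, float]  # (feature_type, value or predicate, multiplier)


def adjust_target(dist: FeatureDistribution,
                  adjustments: Sequence[Adjustment]) -> FeatureDistribution:
    """Multiply matched values in listed order, then renormalize per type.

    A percentage increase of 800% corresponds to multiplier 9; a 50%
    reduction to multiplier 0.5. The value selector is either a literal
    value or a ``Callable[[str], bool]`` predicate.
    """
    out = {ft: dict(table) for ft, table in dist.probs.items()}
    touched: set[str] = set()
    for ft, selector, multiplier in adjustments:
        if multiplier <= 0:
            raise SamplerConfigError(f"multiplier must be positive, got {multiplier}")
        table = out.get(ft)
        if table is None:
            continue
        if callable(selector):
            matched = [v for v in table if selector(v)]
        else:
            matched = [selector] if selector in table else []
        for v in matched:
            table[v] *= multiplier
        touched.add(ft)
    for ft in touched:
        z = sum(out[ft].values())
        if z:
            out[ft] = {v: p / z for v, p in out[ft].items()}
    return FeatureDistribution(probs=out, epsilon=dist.epsilon)


def kl_divergence(p: FeatureDistribution, q: FeatureDistribution,
                  weights: Optional[dict[str, float]] = None) -> float:
    """Weighted sum over feature types of sum_v p(v) ln(p(v)/q(v)).

    Convention 0 ln 0 = 0; q(v) = 0 with p(v) > 0 yields ``inf`` (never the
    case after smoothing).
    """
    total = 0.0
    for ft, p_table in p.probs.items():
        q_table = q.probs.get(ft, {})
        w = 1.0 if weights is None else weights.get(ft, 1.0)
        if w == 0.0 or not p_table:
            continue
        term = 0.0
        for v, pv in p_table.items():
            if pv <= 0.0:
                continue
            qv = q_table.get(v, 0.0)
            if qv <= 0.0:
                return math.inf
            term += pv * math.log(pv / qv)
        total += w * term
    return total


@dataclass
class SamplerConfig:
    temperature: float = 1.6
    adjustments: list[Adjustment] = field(default_factory=list)
    n_select: int = 10
    max_per_article: int = 2
    candidate_subsample: Optional[int] = None  # None = full scan <= 10_000
    feature_weights: dict[str, float] = field(default_factory=dict)
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise SamplerConfigError("temperature must be positive")
        for _, _, m in self.adjustments:
            if m <= 0:
                raise SamplerConfigError("adjustment multipliers must be positive")


def build_target(pool_features: Sequence[FeatureVector],
                 config: SamplerConfig) -> FeatureDistribution:
    """Pool empirical distribution, tempered then adjusted."""
    dist = empirical_distribution(pool_features, epsilon=config.epsilon)
    dist = temper(dist, config.temperature)
    return adjust_target(dist, config.adjustments)


def greedy_select(pool: Sequence[tuple[Passage, FeatureVector]],
                  target: FeatureDistribution,
                  config: SamplerConfig) -> list[int]:
    """Greedy KL minimization; returns selected pool indices in pick order.

    At each step a seeded random subsample of unselected candidates is
    scored; the candidate minimizing KL(selected + candidate, target) is
    added (ties broken by lowest pool index). Candidates whose article
    already holds ``max_per_article`` selections are skipped.
    """
    n = len(pool)
    if config.n_select > n:
        raise SamplerConfigError("n_select exceeds pool size")
    articles = [p.doc_id for p, _ in pool]
    cap = config.max_per_article if config.max_per_article else n
    n_articles = len(set(articles))
    if config.n_select > n_articles * cap:
        raise SamplerConfigError(
            f"infeasible: n_select={config.n_select} > {n_articles} articles x cap {cap}")
    rng = np.random.default_rng(config.seed)
    subsample = config.candidate_subsample
    if subsample is None:
        subsample = n if n <= 10_000 else 2_000

    # running fractional mass per feature type/value for the selected set
    sel_mass: dict[str, dict[str, float]] = {ft: {} for ft in target.probs}
    vocab = {ft: set(table) for ft, table in target.probs.items()}
    selected: list[int] = []
    per_article: dict[str, int] = {}
    eps = config.epsilon
    weights = config.feature_weights

    def kl_with(fv: FeatureVector) -> float:
        total = 0.0
        n_sel = len(selected) + 1
        for ft, q_table in target.probs.items():
            w = weights.get(ft, 1.0) if weights else 1.0
            if w == 0.0:
                continue
            masses = dict(sel_mass[ft])
            for v, m in fv.get(ft, {}).items():
                masses[v] = masses.get(v, 0.0) + m
            values = vocab[ft] | set(masses)
            z = sum(masses.values()) + eps * len(values)
            if z <= 0:
                continue
            term = 0.0
            for v in values:
                pv = (masses.get(v, 0.0) + eps) / z
                qv = q_table.get(v, 0.0)
                if qv <= 0.0:
                    qv = eps / (1.0 + eps * len(values))  # unseen-in-target floor
                term += pv * math.log(pv / qv)
            total += w * term
        return total

    unselected = list(range(n))
    for _ in range(config.n_select):
        eligible = [i for i in unselected
                    if per_article.get(articles[i], 0) < cap]
        if not eligible:
            raise SamplerConfigError("article cap exhausted the eligible pool")
        if len(eligible) > subsample:
            chosen = rng.choice(len(eligible), size=subsample, replace=False)
            candidates = sorted(eligible[int(j)] for j in chosen)
        else:
            candidates = eligible
        best_idx = None
        best_kl = math.inf
        for i in candidates:
            score = kl_with(pool[i][1])
            if score < best_kl - 1e-15:
                best_kl = score
                best_idx = i
        selected.append(best_idx)
        unselected.remove(best_idx)
        per_article[articles[best_idx]] = per_article.get(articles[best_idx], 0) + 1
        for ft, table in pool[best_idx][1].items():
            if ft not in sel_mass:
                continue
            bucket = sel_mass[ft]
            for v, m in table.items():
                bucket[v] = bucket.get(v, 0.0) + m
    return selected


def selection_kl(pool: Sequence[tuple[Passage, FeatureVector]],
                 indices: Sequence[int], target: FeatureDistribution,
                 config: Optional[SamplerConfig] = None) -> float:
    """KL(selected-set distribution, target) for an arbitrary index set."""
    config = config or SamplerConfig()
    vocab = {ft: set(table) for ft, table in target.probs.items()}
    dist = empirical_distribution([pool[i][1] for i in indices],
                                  epsilon=config.epsilon, vocab=vocab)
    # floor target values missing from the smoothed selected vocabulary
    q_probs = {}
    for ft, table in dist.probs.items():
        q_table = dict(target.probs.get(ft, {}))
        floor = config.epsilon / (1.0 + config.epsilon * len(table))
        for v in table:
            q_table.setdefault(v, floor)
        q_probs[ft] = q_table
    return kl_divergence(dist, FeatureDistribution(q_probs, config.epsilon),
                         weights=config.feature_weights or None)
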