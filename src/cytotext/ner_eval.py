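"""Span-level scoring of tagger predictions against gold annotations.

Any tagger that emits BioC predictions can be scored; no model code lives
here. Matching is one-to-one: each predicted annotation may match at most
one reference annotation and vice versa. Micro-averaging across passages;
zero-division convention P = R = F1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus_model import AnnotatedCorpus, CellAnnotation

SPAN_MODES = ("exact", "approx")
LABEL_MODES = ("typed", "merged")


def _label(ann: CellAnnotation, label_mode: str) -> str:
    return "mention" if label_mode == "merged" else ann.entity_type


def match_annotations(gold: Sequence[CellAnnotation],
                      pred: Sequence[CellAnnotation],
                      span_mode: str = "exact",
                      label_mode: str = "typed") -> list[tuple[int, int]]:
    """One-to-one matching within a passage; returns (gold idx, pred idx) pairs.

    Exact mode requires identical (start, end) and, if typed, identical
    entity type. Approx mode requires at least one character of span
    overlap. Greedy resolution order: gold start offset, then largest
    overlap, then lowest prediction index.
    """
    if span_mode not in SPAN_MODES:
        raise ValueError(f"unknown span mode {span_mode!r}")
    if label_mode not in LABEL_MODES:
        raise ValueError(f"unknown label mode {label_mode!r}")
    pairs: list[tuple[int, int]] = []
    used_pred: set[int] = set()
    order = sorted(range(len(gold)), key=lambda g: (gold[g].span.start, gold[g].span.end))
    for g in order:
        ga = gold[g]
        best: Optional[int] = None
        best_overlap = 0
        for p, pa in enumerate(pred):
            if p in used_pred:
                continue
            if _label(ga, label_mode) != _label(pa, label_mode):
                continue
            if span_mode == "exact":
                if (pa.span.start, pa.span.end) == (ga.span.start, ga.span.end):
                    best = p
                    break
            else:
                overlap = (min(ga.span.end, pa.span.end)
                           - max(ga.span.start, pa.span.start))
                if overlap > best_overlap:
                    best_overlap = overlap
                    best = p
        if best is not None:
            used_pred.add(best)
            pairs.append((g, best))
    return pairs


@dataclass
class TypeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class NerScore:
    span_mode: str
    label_mode: str
    overall: TypeCounts = field(default_factory=TypeCounts)
    per_type: dict[str, TypeCounts] = field(default_factory=dict)

    @property
    def f1(self) -> float:
        return self.overall.f1


def score_ner(gold: AnnotatedCorpus, pred: AnnotatedCorpus,
              span_mode: str = "exact", label_mode: str = "typed") -> NerScore:
    """Micro-aggregated P/R/F1 over all passages, per entity type and overall."""
    if len(gold.passages) != len(pred.passages):
        raise ValueError("gold and prediction corpora differ in passage count")
    score = NerScore(span_mode=span_mode, label_mode=label_mode)

    def bucket(entity_type: str) -> TypeCounts:
        return score.per_type.setdefault(entity_type, TypeCounts())

    for gp, pp in zip(gold.passages, pred.passages):
        pairs = match_annotations(gp.annotations, pp.annotations, span_mode, label_mode)
        matched_gold = {g for g, _ in pairs}
        matched_pred = {p for _, p in pairs}
        for g, _ in pairs:
            score.overall.tp += 1
            bucket(gp.annotations[g].entity_type).tp += 1
        for g, ann in enumerate(gp.annotations):
            if g not in matched_gold:
                score.overall.fn += 1
                bucket(ann.entity_type).fn += 1
        for p, ann in enumerate(pp.annotations):
            if p not in matched_pred:
                score.overall.fp += 1
                bucket(ann.entity_type).fp += 1
    return score
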