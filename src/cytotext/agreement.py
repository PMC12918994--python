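"""Inter-annotator agreement and automated inconsistency flagging.

Agreement is pooled micro-F1 between two annotators' span sets under four
strictness variants; related-match identifiers are coerced to "no ID"
before any identifier comparison, since several combinations of related
identifiers are usually acceptable.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus_model import AnnotatedCorpus, CellAnnotation, Passage

AGREEMENT_MODES = ("strict_span_id", "strict_span", "strict_id", "approx_span")

DEFAULT_SUBSET_TERMS = ("subset", "subsets", "subtype", "subtypes",
                        "subpopulation", "subpopulations", "class", "classes")


class AlignmentError(ValueError):
    """The two corpora do not reference the same passages."""


@dataclass
class ModeScore:
    matched: int
    n_a: int
    n_b: int

    @property
    def precision(self) -> float:
        return self.matched / self.n_b if self.n_b else 0.0

    @property
    def recall(self) -> float:
        return self.matched / self.n_a if self.n_a else 0.0

    @property
    def f1(self) -> float:
        denom = self.n_a + self.n_b
        return 2.0 * self.matched / denom if denom else 0.0


@dataclass
class AgreementReport:
    mode: str
    merge_labels: bool
    overall: ModeScore
    by_passage_type: dict[str, ModeScore] = field(default_factory=dict)

    @property
    def f1(self) -> float:
        return self.overall.f1


def _label(ann: CellAnnotation, merge_labels: bool) -> str:
    return "mention" if merge_labels else ann.entity_type


def _exact_ids(ann: CellAnnotation) -> frozenset[str]:
    # related -> "no ID" coercion happens here: only exact links survive
    return ann.exact_ids


def _match_counts(ann_a: Sequence[CellAnnotation], ann_b: Sequence[CellAnnotation],
                  mode: str, merge_labels: bool) -> tuple[int, int, int]:
    """(matched, |a|, |b|) for one passage."""
    if mode == "strict_span_id":
        keys_a = Counter((a.span.start, a.span.end, _label(a, merge_labels),
                          _exact_ids(a)) for a in ann_a)
        keys_b = Counter((b.span.start, b.span.end, _label(b, merge_labels),
                          _exact_ids(b)) for b in ann_b)
        matched = sum((keys_a & keys_b).values())
        return matched, len(ann_a), len(ann_b)
    if mode == "strict_span":
        keys_a = Counter((a.span.start, a.span.end, _label(a, merge_labels))
                         for a in ann_a)
        keys_b = Counter((b.span.start, b.span.end, _label(b, merge_labels))
                         for b in ann_b)
        matched = sum((keys_a & keys_b).values())
        return matched, len(ann_a), len(ann_b)
    if mode == "strict_id":
        # set of identifiers present anywhere in the passage
        ids_a = set().union(*[_exact_ids(a) for a in ann_a]) if ann_a else set()
        ids_b = set().union(*[_exact_ids(b) for b in ann_b]) if ann_b else set()
        return len(ids_a & ids_b), len(ids_a), len(ids_b)
    if mode == "approx_span":
        # greedy one-to-one overlap matching, annotator A processed by start
        used_b: set[int] = set()
        matched = 0
        for a in sorted(ann_a, key=lambda x: (x.span.start, x.span.end)):
            best_j: Optional[int] = None
            best_overlap = 0
            for j, b in enumerate(ann_b):
                if j in used_b:
                    continue
                if _label(a, merge_labels) != _label(b, merge_labels):
                    continue
                overlap = (min(a.span.end, b.span.end)
                           - max(a.span.start, b.span.start))
                if overlap > best_overlap:
                    best_overlap = overlap
                    best_j = j
            if best_j is not None:
                used_b.add(best_j)
                matched += 1
        return matched, len(ann_a), len(ann_b)
    raise ValueError(f"unknown agreement mode {mode!r}")


def iaa(corpus_a: AnnotatedCorpus, corpus_b: AnnotatedCorpus, mode: str,
        merge_labels: bool = False) -> AgreementReport:
    """Pooled micro-F1 agreement between two annotator copies.

    ``corpus_a`` and ``corpus_b`` must contain the same passages in the
    same order (the annotations may differ). F1 is symmetric: swapping the
    annotators swaps precision and recall but leaves F1 unchanged.
    """
    if len(corpus_a.passages) != len(corpus_b.passages):
        raise AlignmentError("annotator copies differ in passage count")
    pooled = [0, 0, 0]
    by_type: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0])
    for pa, pb in zip(corpus_a.passages, corpus_b.passages):
        if pa.text != pb.text or pa.doc_id != pb.doc_id:
            raise AlignmentError(f"passage mismatch in document {pa.doc_id}")
        m, na, nb = _match_counts(pa.annotations, pb.annotations, mode, merge_labels)
        for acc in (pooled, by_type[pa.passage_type]):
            acc[0] += m
            acc[1] += na
            acc[2] += nb
    return AgreementReport(
        mode=mode, merge_labels=merge_labels,
        overall=ModeScore(*pooled),
        by_passage_type={pt: ModeScore(*acc) for pt, acc in sorted(by_type.items())},
    )


def iaa_all_modes(corpus_a: AnnotatedCorpus, corpus_b: AnnotatedCorpus,
                  merge_labels: bool = False) -> dict[str, AgreementReport]:
    return {mode: iaa(corpus_a, corpus_b, mode, merge_labels)
            for mode in AGREEMENT_MODES}


@dataclass(frozen=True)
class ConsistencyFlag:
    kind: str  # divergent_link | subset_phrase
    passage_index: int
    ann_id: str
    mention: str
    detail: str


def flag_divergent_links(corpus: AnnotatedCorpus, min_support: int = 2) -> list[ConsistencyFlag]:
    """Flag mention-identifier pairs diverging from the mention's modal pattern.

    For each case-folded mention string with at least ``min_support``
    occurrences, occurrences whose exact-match identifier set differs from
    the modal identifier set are flagged; modal ties flag nothing.
    """
    occurrences: dict[str, list[tuple[int, CellAnnotation]]] = defaultdict(list)
    for i, _, ann in corpus.annotations():
        occurrences[ann.span.text.casefold()].append((i, ann))
    flags: list[ConsistencyFlag] = []
    for mention, occs in occurrences.items():
        if len(occs) < min_support:
            continue
        patterns = Counter(_exact_ids(ann) for _, ann in occs)
        ranked = patterns.most_common()
        if len(ranked) < 2:
            continue
        if ranked[0][1] == ranked[1][1]:
            continue  # modal tie: no predominant pattern
        modal = ranked[0][0]
        for i, ann in occs:
            if _exact_ids(ann) != modal:
                flags.append(ConsistencyFlag(
                    kind="divergent_link", passage_index=i, ann_id=ann.ann_id,
                    mention=ann.span.text,
                    detail=f"ids {sorted(_exact_ids(ann))} vs modal {sorted(modal)}"))
    return flags


def flag_subset_phrases(corpus: AnnotatedCorpus,
                        subset_terms: Iterable[str] = DEFAULT_SUBSET_TERMS
                        ) -> list[ConsistencyFlag]:
    """Flag non-vague annotations immediately followed by a subset descriptor.

    The extended phrase (annotation + descriptor) should itself be annotated
    as a vague population; when a vague annotation already covers it, no
    flag is emitted.
    """
    terms = sorted({t.casefold() for t in subset_terms}, key=len, reverse=True)
    if not terms:
        raise ValueError("subset_terms must be nonempty")
    flags: list[ConsistencyFlag] = []
    for i, passage, ann in corpus.annotations():
        if ann.entity_type == "vague":
            continue
        tail = passage.text[ann.span.end:]
        stripped = tail.lstrip()
        lead_ws = len(tail) - len(stripped)
        low = stripped.casefold()
        hit = None
        for term in terms:
            if low.startswith(term):
                after = low[len(term):]
                if not after or not after[0].isalnum():
                    hit = term
                    break
        if hit is None:
            continue
        phrase_end = ann.span.end + lead_ws + len(hit)
        covered = any(
            other.entity_type == "vague"
            and other.span.start <= ann.span.start
            and other.span.end >= phrase_end
            for other in passage.annotations)
        if not covered:
            flags.append(ConsistencyFlag(
                kind="subset_phrase", passage_index=i, ann_id=ann.ann_id,
                mention=ann.span.text,
                detail=f"followed by descriptor {hit!r} without covering vague annotation"))
    return flags
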