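"""Embedding-based entity linking against an ontology, and its evaluation.

The embedder is a plug-in contract (text -> unit-norm vector); the shipped
default is a deterministic hashed character-trigram bag, which gives
meaningful string similarity without any pretrained model. Evaluation
covers single-link precision/recall/F1 with exact-only vs all-identifier
gold semantics, annotation-level top-k recall, and novelty-detection ROC
analysis of linker confidence.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol, Sequence

import numpy as np

from .corpus_model import AnnotatedCorpus, CellAnnotation, Ontology


class Embedder(Protocol):
    """Contract: deterministic text -> fixed-length unit-norm vector."""

    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashedNGramEmbedder:
    """Hashed character n-gram bag, L2-normalized.

    Deterministic across processes (MD5-based bucketing, no PYTHONHASHSEED
    dependence). Identical inputs give identical vectors; string overlap
    translates into cosine similarity.
    """

    def __init__(self, dim: int = 512, n: int = 3) -> None:
        self.dim = dim
        self.n = n

    def embed(self, text: str) -> np.ndarray:
        padded = f" {text.casefold()} "
        vec = np.zeros(self.dim, dtype=float)
        if len(padded) < self.n:
            padded = padded.ljust(self.n)
        for i in range(len(padded) - self.n + 1):
            gram = padded[i:i + self.n]
            digest = hashlib.md5(gram.encode("utf-8")).digest()
            vec[int.from_bytes(digest[:4], "little") % self.dim] += 1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


# ---------------------------------------------------------------------------
# Mention preprocessing
# ---------------------------------------------------------------------------

def stem_plural(word: str) -> str:
    """Conservative plural stripping.

    The trailing "s" is removed only when the stem has >= 3 letters and the
    word does not end in "ss", "us", "is", "as", or "ys"; idempotent.
    """
    low = word.casefold()
    if (low.endswith("s") and len(word) >= 4
            and not low.endswith(("ss", "us", "is", "as", "ys"))):
        return word[:-1]
    return word


def preprocess_mention(text: str, abbreviation_map: Optional[dict[str, str]] = None,
                       stem_plurals: bool = True) -> str:
    """Abbreviation expansion (longest match first) then plural stemming.

    The abbreviation map is an input; its construction (e.g. by an external
    abbreviation detector over the full article) is out of scope. A plural
    abbreviation ("Tregs") expands via its stemmed form.
    """
    abbreviation_map = abbreviation_map or {}
    out: list[str] = []
    for token in text.split():
        if token in abbreviation_map:
            out.append(abbreviation_map[token])
            continue
        stemmed = stem_plural(token) if stem_plurals else token
        if stemmed != token and stemmed in abbreviation_map:
            out.append(abbreviation_map[stemmed])
            continue
        out.append(stemmed if stem_plurals else token)
    return " ".join(out)


# ---------------------------------------------------------------------------
# Candidate retrieval
# ---------------------------------------------------------------------------

class OntologyIndex:
    """Embedded labels and synonyms of every non-obsolete ontology term."""

    def __init__(self, ontology: Ontology, embedder: Embedder) -> None:
        self.embedder = embedder
        rows: list[np.ndarray] = []
        self.row_terms: list[str] = []
        for term_id in sorted(ontology.terms):
            term = ontology.terms[term_id]
            if term.obsolete:
                continue
            names = [term.label or term_id] + list(term.synonyms)
            for name in names:
                rows.append(embedder.embed(name))
                self.row_terms.append(term_id)
        if not rows:
            raise ValueError("ontology contributes no index vectors")
        self.matrix = np.vstack(rows)


@dataclass
class LinkPrediction:
    mention: str
    ranking: list[tuple[str, float]]  # (term id, cosine), scores nonincreasing

    @property
    def top_id(self) -> str:
        return self.ranking[0][0]

    @property
    def confidence(self) -> float:
        return self.ranking[0][1]

    def top_ids(self, k: int) -> list[str]:
        return [t for t, _ in self.ranking[:k]]


def link_topk(mention: str, index: OntologyIndex, embedder: Optional[Embedder] = None,
              k: int = 10) -> LinkPrediction:
    """Rank terms by best cosine over their label+synonym vectors.

    Ties are broken by lexicographic term id for reproducibility.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    embedder = embedder or index.embedder
    query = embedder.embed(mention)
    sims = index.matrix @ query
    best: dict[str, float] = {}
    for term_id, sim in zip(index.row_terms, sims):
        s = float(sim)
        if term_id not in best or s > best[term_id]:
            best[term_id] = s
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return LinkPrediction(mention=mention, ranking=ranked[:k])


def link_corpus(corpus: AnnotatedCorpus, index: OntologyIndex,
                embedder: Optional[Embedder] = None, k: int = 10,
                abbreviation_map: Optional[dict[str, str]] = None,
                stem_plurals: bool = True,
                include_vague: bool = False) -> dict[tuple[int, int], LinkPrediction]:
    """Link every (non-vague, by default) annotation; keyed by (passage, ann) index."""
    preds: dict[tuple[int, int], LinkPrediction] = {}
    for i, passage in enumerate(corpus.passages):
        for j, ann in enumerate(passage.annotations):
            if ann.entity_type == "vague" and not include_vague:
                continue
            mention = preprocess_mention(ann.span.text, abbreviation_map, stem_plurals)
            preds[(i, j)] = link_topk(mention, index, embedder, k)
    return preds


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

EL_MODES = ("exact_only", "all_ids")


@dataclass
class ElCounts:
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
class ElScore:
    mode: str
    overall: ElCounts = field(default_factory=ElCounts)
    per_type: dict[str, ElCounts] = field(default_factory=dict)
    topk_recall: dict[int, float] = field(default_factory=dict)

    @property
    def f1(self) -> float:
        return self.overall.f1


def _gold_ids(ann: CellAnnotation, mode: str) -> frozenset[str]:
    if mode == "exact_only":
        return ann.exact_ids
    return ann.all_ids


def score_single_link(gold: AnnotatedCorpus,
                      predictions: dict[tuple[int, int], str | LinkPrediction],
                      mode: str = "all_ids") -> ElScore:
    """Micro (annotation, id)-pair counts for single-identifier predictions.

    Per annotation: TP if the predicted id is in the gold id set, else FP;
    FN is the number of unrecovered gold ids. In ``exact_only`` mode,
    annotations without an exact-match link are excluded entirely and gold
    sets reduce to exact ids. In ``all_ids`` mode, unlinked gold
    annotations contribute zero gold ids, so any prediction on them counts
    as a false positive. Multi-id predictions violate the single-link
    contract and raise.
    """
    if mode not in EL_MODES:
        raise ValueError(f"unknown EL mode {mode!r}")
    score = ElScore(mode=mode)

    def bucket(entity_type: str) -> ElCounts:
        return score.per_type.setdefault(entity_type, ElCounts())

    for i, passage in enumerate(gold.passages):
        for j, ann in enumerate(passage.annotations):
            if ann.entity_type == "vague":
                continue
            if mode == "exact_only" and not ann.exact_ids:
                continue
            gold_ids = _gold_ids(ann, mode)
            pred = predictions.get((i, j))
            if isinstance(pred, LinkPrediction):
                pred_id = pred.top_id
            elif isinstance(pred, (list, tuple, set, frozenset)):
                raise ValueError("single-link predictions must carry exactly one id")
            else:
                pred_id = pred
            tp = fp = 0
            if pred_id is not None:
                if pred_id in gold_ids:
                    tp = 1
                else:
                    fp = 1
            fn = len(gold_ids) - tp
            for counts in (score.overall, bucket(ann.entity_type)):
                counts.tp += tp
                counts.fp += fp
                counts.fn += fn
    return score


def topk_recall(gold: AnnotatedCorpus,
                predictions: dict[tuple[int, int], LinkPrediction],
                k: int) -> float:
    """Fraction of gold-linked annotations whose gold id set (exact and
    related pooled) intersects the top-k predicted terms."""
    hits = 0
    total = 0
    for i, passage in enumerate(gold.passages):
        for j, ann in enumerate(passage.annotations):
            gold_ids = ann.all_ids
            if not gold_ids:
                continue
            total += 1
            pred = predictions.get((i, j))
            if pred is not None and gold_ids & set(pred.top_ids(k)):
                hits += 1
    return hits / total if total else 0.0


def novelty_roc(scored: Sequence[tuple[float, bool]]
                ) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUROC for confidence as a has-exact-match detector.

    AUROC is computed by the rank statistic (concordant pairs plus half
    ties over n_pos * n_neg); the curve lists (FPR, TPR) at every distinct
    score threshold, from (0, 0) to (1, 1).
    """
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([bool(l) for _, l in scored])
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    # rank formula (Mann-Whitney U with midranks for ties)
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auroc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    # curve: sweep thresholds over distinct scores, descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scored)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            if sorted_labels[j]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points, auroc
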