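"""Compositional naming-motif labeling and prevalence statistics.

Cell population names are decomposed into motifs from a closed vocabulary
of 14 types. Manually mapped motifs are placed first (longest
non-overlapping matches); remaining 1-3 token candidates are labeled by a
multinomial logistic-regression classifier over embedding vectors and
placed in order of classifier margin. Each annotation receives fractional
lineage weights through its ontology links, and per-(lineage, motif)
prevalences are compared with exact binomial / Fisher tests under
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .corpus_model import AnnotatedCorpus, CellAnnotation, Ontology, OntologyLink, ancestors
from .linking_eval import Embedder, preprocess_mention, stem_plural

logger = logging.getLogger(__name__)

#: Closed vocabulary of motif types. Exactly 14 members.
MOTIF_TYPES: tuple[str, ...] = (
    "root",
    "anatomical_context",
    "lineage",
    "molecular_signature",
    "appearance",
    "functional_role",
    "developmental_stage",
    "state",
    "variant",
    "molecular_signaling",
    "disease",
    "eponym",
    "stimulus",
    "species_sex",
)

DEFAULT_STOPWORDS = frozenset({"and", "or", "of", "the", "a", "an", "with", "to", "in"})

MAX_CANDIDATE_LEN = 3

#: Keywords marking artificial or abnormal cells, excluded from scope by the
#: default corpus filter.
DEFAULT_SCOPE_EXCLUSION_KEYWORDS = ("cultured", "ipsc-derived", "abnormal", "infected")


def default_lemmatize(text: str) -> list[str]:
    """Pluggable lemmatizer contract; default = lowercase + plural stemmer."""
    return [stem_plural(tok.casefold()) for tok in text.split()]


@dataclass(frozen=True)
class MotifSpan:
    start: int  # token index, half-open range
    end: int
    motif_type: str
    source: str  # manual | classifier
    margin: Optional[float] = None

    def __post_init__(self) -> None:
        if self.motif_type not in MOTIF_TYPES:
            raise ValueError(f"unknown motif type {self.motif_type!r}")
        if self.source not in ("manual", "classifier"):
            raise ValueError(f"unknown motif source {self.source!r}")

    def overlaps(self, other: "MotifSpan") -> bool:
        return self.start < other.end and other.start < self.end


def extract_candidates(tokens: Sequence[str],
                       manual_spans: Sequence[tuple[int, int]] = (),
                       stopwords: Iterable[str] = DEFAULT_STOPWORDS
                       ) -> list[tuple[int, int]]:
    """All 1-3 token contiguous ranges (overlaps permitted) that neither
    intersect a manually labeled span nor begin/end with a stop word."""
    stop = set(stopwords)
    for s, e in manual_spans:
        if not (0 <= s < e <= len(tokens)):
            raise ValueError(f"manual span ({s},{e}) outside token list")
    out: list[tuple[int, int]] = []
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, min(i + MAX_CANDIDATE_LEN, n) + 1):
            if tokens[i] in stop or tokens[j - 1] in stop:
                continue
            if any(i < e and s < j for s, e in manual_spans):
                continue
            out.append((i, j))
    return out


def apply_manual_map(tokens: Sequence[str],
                     manual_map: Mapping[tuple[str, ...], str]) -> list[MotifSpan]:
    """Greedy left-to-right longest non-overlapping matches of the manual map."""
    if not manual_map:
        return []
    max_len = max(len(k) for k in manual_map)
    spans: list[MotifSpan] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(tokens[i:i + length])
            if key in manual_map:
                spans.append(MotifSpan(i, i + length, manual_map[key], "manual"))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return spans


class MotifClassifier:
    """Multinomial logistic regression over embedding vectors."""

    def __init__(self, model, embedder: Embedder, classes: np.ndarray) -> None:
        self._model = model
        self._embedder = embedder
        self.classes = classes

    def predict_proba(self, phrase: str) -> np.ndarray:
        vec = self._embedder.embed(phrase).reshape(1, -1)
        return self._model.predict_proba(vec)[0]

    def predict_with_margin(self, phrase: str) -> tuple[str, float]:
        """Predicted motif type and margin (top minus second probability)."""
        probs = self.predict_proba(phrase)
        order = np.argsort(-probs)
        top = probs[order[0]]
        second = probs[order[1]] if len(probs) > 1 else 0.0
        return str(self.classes[order[0]]), float(top - second)


def train_motif_classifier(labeled: Sequence[tuple[str, str]], embedder: Embedder,
                           seed: int = 0) -> MotifClassifier:
    """Fit the motif classifier on (phrase, motif_type) examples."""
    from sklearn.linear_model import LogisticRegression

    if len({m for _, m in labeled}) < 2:
        raise ValueError("need at least two motif classes to train")
    for _, motif in labeled:
        if motif not in MOTIF_TYPES:
            raise ValueError(f"unknown motif type {motif!r}")
    X = np.vstack([embedder.embed(text) for text, _ in labeled])
    y = np.array([motif for _, motif in labeled])
    model = LogisticRegression(max_iter=2000, random_state=seed)
    model.fit(X, y)
    return MotifClassifier(model, embedder, model.classes_)


def classifier_cv_accuracy(labeled: Sequence[tuple[str, str]], embedder: Embedder,
                           n_splits: int = 10, n_repeats: int = 5,
                           seed: int = 0) -> float:
    """Accuracy under repeated stratified cross-validation (10-fold x 5 by
    default), the protocol used to estimate classifier quality."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

    X = np.vstack([embedder.embed(text) for text, _ in labeled])
    y = np.array([motif for _, motif in labeled])
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=seed)
    scores = cross_val_score(LogisticRegression(max_iter=2000, random_state=seed),
                             X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def assign_motifs(tokens: Sequence[str],
                  manual_map: Mapping[tuple[str, ...], str],
                  classifier: Optional[MotifClassifier] = None,
                  stopwords: Iterable[str] = DEFAULT_STOPWORDS,
                  margin_order: str = "increasing") -> list[MotifSpan]:
    """Manual spans first, then classifier candidates by margin order.

    Candidates are sorted by margin (ascending by default; ``margin_order=
    "decreasing"`` flips it — the placement direction is configurable) and
    added iff they do not overlap an already-placed span. Placed spans are
    pairwise disjoint by construction.
    """
    if margin_order not in ("increasing", "decreasing"):
        raise ValueError("margin_order must be 'increasing' or 'decreasing'")
    placed = apply_manual_map(tokens, manual_map)
    if classifier is None:
        return placed
    candidates = extract_candidates(tokens, [(s.start, s.end) for s in placed],
                                    stopwords)
    scored: list[MotifSpan] = []
    for i, j in candidates:
        phrase = " ".join(tokens[i:j])
        motif, margin = classifier.predict_with_margin(phrase)
        scored.append(MotifSpan(i, j, motif, "classifier", margin))
    reverse = margin_order == "decreasing"
    scored.sort(key=lambda s: ((-s.margin if reverse else s.margin), s.start, s.end))
    for span in scored:
        if not any(span.overlaps(p) for p in placed):
            placed.append(span)
    return sorted(placed, key=lambda s: (s.start, s.end))


# ---------------------------------------------------------------------------
# Fractional lineage assignment
# ---------------------------------------------------------------------------

def assign_lineages(links: Sequence[OntologyLink | str], ontology: Ontology,
                    lineage_map: Mapping[str, set[str]]) -> dict[str, float]:
    """Fractional lineage weights for one annotation.

    Each link carries weight ``1/len(links)``, split equally across the
    lineages whose root set intersects the linked term's self-plus-ancestors
    closure. Links hitting no lineage contribute nothing; if no link hits a
    lineage the annotation is excluded (empty mapping). Nonempty results are
    normalized to sum to 1.
    """
    weights: dict[str, float] = {}
    if not links:
        return weights
    per_link = 1.0 / len(links)
    for link in links:
        term_id = link.term_id if isinstance(link, OntologyLink) else link
        resolved = ontology.resolve(term_id)
        if resolved is None:
            logger.warning("unresolved link %s skipped in lineage assignment", term_id)
            continue
        closure = ancestors(ontology, resolved) | {resolved}
        hit = [lin for lin, roots in lineage_map.items() if roots & closure]
        if not hit:
            continue
        share = per_link / len(hit)
        for lin in hit:
            weights[lin] = weights.get(lin, 0.0) + share
    total = sum(weights.values())
    if total > 0 and abs(total - 1.0) > 1e-12:
        weights = {lin: w / total for lin, w in weights.items()}
    return weights


# ---------------------------------------------------------------------------
# Prevalence table
# ---------------------------------------------------------------------------

ALL_LINEAGES = "ALL"


@dataclass
class PrevalenceTable:
    """Weighted with-motif counts and totals per (lineage, motif type).

    ``num[(lineage, motif)]`` is the fractional count of mentions containing
    the motif at least once; ``den[lineage]`` the total fractional mention
    count. The baseline row :data:`ALL_LINEAGES` pools all lineages.
    """

    num: dict[tuple[str, str], float] = field(default_factory=dict)
    den: dict[str, float] = field(default_factory=dict)
    motifs: tuple[str, ...] = MOTIF_TYPES

    def lineages(self, include_all: bool = False) -> list[str]:
        lins = sorted(l for l in self.den if l != ALL_LINEAGES)
        return lins + [ALL_LINEAGES] if include_all and ALL_LINEAGES in self.den else lins

    def prevalence(self, lineage: str, motif: str) -> float:
        d = self.den.get(lineage, 0.0)
        return self.num.get((lineage, motif), 0.0) / d if d else 0.0


def prevalence_table(records: Sequence[tuple[dict[str, float], set[str]]],
                     motifs: tuple[str, ...] = MOTIF_TYPES) -> PrevalenceTable:
    """Build the table from (lineage weights, motif types present) records.

    Records with zero total lineage weight are skipped (lineage-less
    annotations); lineages ending with zero denominator are omitted with a
    notice.
    """
    table = PrevalenceTable(motifs=motifs)
    for weights, present in records:
        total = sum(weights.values())
        if total <= 0:
            continue
        for lineage, w in weights.items():
            table.den[lineage] = table.den.get(lineage, 0.0) + w
            for motif in present:
                key = (lineage, motif)
                table.num[key] = table.num.get(key, 0.0) + w
        table.den[ALL_LINEAGES] = table.den.get(ALL_LINEAGES, 0.0) + total
        for motif in present:
            key = (ALL_LINEAGES, motif)
            table.num[key] = table.num.get(key, 0.0) + total
    for lineage in [l for l, d in table.den.items() if d <= 0]:
        logger.warning("lineage %s has zero denominator; omitted", lineage)
        del table.den[lineage]
    return table


# ---------------------------------------------------------------------------
# Exact tests and FDR control
# ---------------------------------------------------------------------------

_TIE_TOL = 1.0 + 1e-9


def binom_test_exact(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test (minimum-likelihood method).

    p = sum of Binom(i; n, p0) over all i whose point probability does not
    exceed that of the observed k (within a relative tolerance of 1e-9).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"baseline probability must be in (0, 1), got {p0}")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * _TIE_TOL].sum()))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities not exceeding the observed
    one. Degenerate margins give p = 1 with a notice.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        logger.warning("degenerate margins in Fisher test; p = 1")
        return 1.0
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, total, row1, col1)
    observed = sps.hypergeom.pmf(a, total, row1, col1)
    return float(min(1.0, pmf[pmf <= observed * _TIE_TOL].sum()))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return [float(v) for v in q]


@dataclass
class TestResult:
    lineage: str
    motif_type: str
    k: int
    n: int
    p0: float
    p_value: float
    q_value: float = math.nan
    significant: bool = False
    direction: str = ""  # higher | lower
    test: str = "binomial"  # binomial | fisher


def compare_prevalence(table: PrevalenceTable,
                       reference: Optional[PrevalenceTable] = None,
                       alpha_fdr: float = 0.01) -> list[TestResult]:
    """Exact prevalence tests with joint BH correction at ``alpha_fdr``.

    Without a ``reference``, each (lineage, motif) cell is tested against
    the table's own pooled all-lineage prevalence (inclusive baseline) with
    an exact binomial test. With a reference table, the cell's baseline is
    the corresponding reference prevalence, and additional pooled rows
    compare the two tables' overall rounded with/without counts per motif
    via Fisher's exact test. Fractional counts are rounded half-to-even.
    """
    results: list[TestResult] = []
    lineages = table.lineages()
    for lineage in lineages:
        n = round(table.den.get(lineage, 0.0))
        if n < 1:
            continue
        for motif in table.motifs:
            k = min(round(table.num.get((lineage, motif), 0.0)), n)
            if reference is None:
                p0 = table.prevalence(ALL_LINEAGES, motif)
            else:
                p0 = reference.prevalence(lineage, motif)
            if not (0.0 < p0 < 1.0):
                logger.debug("skipping (%s, %s): degenerate baseline %s",
                             lineage, motif, p0)
                continue
            p = binom_test_exact(k, n, p0)
            obs = k / n
            results.append(TestResult(
                lineage=lineage, motif_type=motif, k=k, n=n, p0=p0, p_value=p,
                direction="higher" if obs > p0 else "lower", test="binomial"))
    if reference is not None and ALL_LINEAGES in table.den and ALL_LINEAGES in reference.den:
        n1 = round(table.den[ALL_LINEAGES])
        n2 = round(reference.den[ALL_LINEAGES])
        for motif in table.motifs:
            k1 = min(round(table.num.get((ALL_LINEAGES, motif), 0.0)), n1)
            k2 = min(round(reference.num.get((ALL_LINEAGES, motif), 0.0)), n2)
            if n1 < 1 or n2 < 1:
                continue
            p = fisher_exact(k1, n1 - k1, k2, n2 - k2)
            obs = k1 / n1
            ref_prev = k2 / n2
            results.append(TestResult(
                lineage=ALL_LINEAGES, motif_type=motif, k=k1, n=n1,
                p0=ref_prev, p_value=p,
                direction="higher" if obs > ref_prev else "lower", test="fisher"))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
        r.significant = q < alpha_fdr
    return results


# ---------------------------------------------------------------------------
# End-to-end corpus labeling
# ---------------------------------------------------------------------------

def eligible_annotations(corpus: AnnotatedCorpus,
                         exclusion_keywords: Sequence[str] = DEFAULT_SCOPE_EXCLUSION_KEYWORDS,
                         drop_multi_id: bool = True
                         ) -> list[tuple[int, int, CellAnnotation]]:
    """Scope filter preceding motif analysis.

    Drops vague and unlinked annotations, multi-identifier (coordination)
    annotations when ``drop_multi_id``, and mentions containing any
    exclusion keyword (artificial/abnormal cell markers).
    """
    keywords = tuple(k.casefold() for k in exclusion_keywords)
    kept: list[tuple[int, int, CellAnnotation]] = []
    for i, passage in enumerate(corpus.passages):
        for j, ann in enumerate(passage.annotations):
            if ann.entity_type == "vague" or not ann.links:
                continue
            if drop_multi_id and len(ann.all_ids) > 1:
                continue
            low = ann.span.text.casefold()
            if any(k in low for k in keywords):
                continue
            kept.append((i, j, ann))
    return kept


def label_corpus_motifs(corpus: AnnotatedCorpus, ontology: Ontology,
                        lineage_map: Mapping[str, set[str]],
                        manual_map: Mapping[tuple[str, ...], str],
                        classifier: Optional[MotifClassifier] = None,
                        abbreviation_map: Optional[dict[str, str]] = None,
                        stopwords: Iterable[str] = DEFAULT_STOPWORDS,
                        margin_order: str = "increasing"
                        ) -> list[tuple[dict[str, float], set[str], list[MotifSpan]]]:
    """Filter, preprocess, motif-label and lineage-weight every annotation.

    Returns one ``(lineage weights, motif types present, motif spans)``
    record per in-scope annotation; feed the first two elements to
    :func:`prevalence_table`.
    """
    records = []
    for _, _, ann in eligible_annotations(corpus):
        weights = assign_lineages(ann.links, ontology, lineage_map)
        if not weights:
            continue
        mention = preprocess_mention(ann.span.text, abbreviation_map)
        tokens = default_lemmatize(mention)
        spans = assign_motifs(tokens, manual_map, classifier, stopwords, margin_order)
        records.append((weights, {s.motif_type for s in spans}, spans))
    return records
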