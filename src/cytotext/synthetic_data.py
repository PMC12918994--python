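"""Seeded generators for every fixture the pipeline needs.

All generators are pure functions of ``(config, seed)``: same inputs,
byte-identical outputs. Generated corpora always satisfy the
:mod:`cytotext.corpus_model` invariants (checked in tests via
:func:`~cytotext.corpus_model.validate_corpus`).

Cell names are assembled from small fixed per-motif-type vocabularies in a
fixed surface order (ending in the lineage root word), so the ground-truth
motif spans are unambiguous and motif-prevalence recovery is testable by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus_model import (
    AnnotatedCorpus,
    CellAnnotation,
    Ontology,
    OntologyLink,
    OntologyTerm,
    Passage,
    Span,
)

# Word lists per motif type. Kept deliberately tiny and non-overlapping so a
# manual lemma->motif map covering them is exact and classifier training data
# is linearly separable by construction.
MOTIF_VOCAB: dict[str, tuple[str, ...]] = {
    "species_sex": ("human", "murine", "male", "female", "porcine"),
    "disease": ("tumor", "asthmatic", "diabetic", "fibrotic", "arthritic"),
    "state": ("naive", "activated", "exhausted", "resting", "senescent"),
    "appearance": ("pyramidal", "spindle", "granular", "stellate", "cuboidal"),
    "functional_role": ("regulatory", "helper", "cytotoxic", "suppressor", "secretory"),
    "variant": ("m1", "m2", "th1", "th17", "type2"),
    "molecular_signaling": ("gabaergic", "dopaminergic", "cholinergic",
                            "adrenergic", "glutamatergic"),
    "stimulus": ("photosensitive", "mechanosensitive", "chemosensitive",
                 "thermosensitive", "osmosensitive"),
    "eponym": ("muller", "purkinje", "langerhans", "kupffer", "schwann"),
    "molecular_signature": ("CD8+", "CD4+", "FOXP3+", "LY6C+", "KLRG1+"),
    "anatomical_context": ("hepatic", "pulmonary", "dermal", "intestinal", "renal"),
    "developmental_stage": ("immature", "mature", "embryonic", "fetal", "neonatal"),
    "lineage": ("lymphoid", "myeloid", "epithelial", "stromal", "neural"),
}

# Surface order of motif slots within a generated name; the root word is
# always last (names are roughly head-final).
NAME_MOTIF_ORDER: tuple[str, ...] = (
    "species_sex", "disease", "state", "appearance", "functional_role",
    "variant", "molecular_signaling", "stimulus", "eponym",
    "molecular_signature", "anatomical_context", "developmental_stage",
    "lineage",
)

DEFAULT_LINEAGES = ("alpha", "beta", "gamma", "delta")

_JOURNALS = ("J Synth Cell", "Toy Biol", "Fixture Rep", "Ann Test Data")
_MESH_CLUSTERS = ("Immune-Anatomy", "Nervous-Anatomy", "Cardio-Disease",
                  "Cancer-Disease", "Digestive-Anatomy")
_PASSAGE_TYPES = ("paragraph", "paragraph", "paragraph", "paragraph",
                  "title", "abstract", "section_header", "caption", "table")


def lineage_root_word(lineage: str) -> str:
    """Deterministic root word for a synthetic lineage (e.g. 'alphacyte')."""
    return f"{lineage}cyte"


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_passages: int = 100
    lineage_roots: tuple[str, ...] = DEFAULT_LINEAGES
    motif_prevalence: dict[tuple[str, str], float] = field(default_factory=dict)
    exact_link_fraction: float = 0.8
    multi_id_fraction: float = 0.0
    vague_fraction: Optional[float] = None  # overrides entity_type_mix[2]
    unlinked_fraction: float = 0.0
    entity_type_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)
    annotations_per_passage: tuple[int, int] = (1, 3)  # inclusive range
    passages_per_article: int = 1
    ontology_depth: int = 3
    ontology_branching: int = 2

    def __post_init__(self) -> None:
        for p in (self.exact_link_fraction, self.multi_id_fraction,
                  self.unlinked_fraction, *self.entity_type_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for p in self.motif_prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"motif prevalence {p} outside [0, 1]")
        if abs(sum(self.entity_type_mix) - 1.0) > 1e-9:
            raise ValueError("entity_type_mix must sum to 1")
        if self.vague_fraction is not None:
            if not 0.0 <= self.vague_fraction <= 1.0:
                raise ValueError("vague_fraction outside [0, 1]")
            rest = 1.0 - self.vague_fraction
            a, b, _ = self.entity_type_mix
            ab = a + b
            self.entity_type_mix = (
                (rest * a / ab if ab else rest, rest * b / ab if ab else 0.0,
                 self.vague_fraction))

    def prevalence(self, lineage: str, motif_type: str) -> float:
        return self.motif_prevalence.get((lineage, motif_type), 0.0)


@dataclass
class TruthRecord:
    """Ground truth for one generated annotation."""

    passage_index: int
    annotation_index: int
    entity_type: str
    term_ids: tuple[str, ...]
    qualifiers: tuple[str, ...]
    lineages: tuple[str, ...]
    motif_spans: tuple[tuple[int, int, str], ...]  # name-relative char spans
    coordination: bool = False


@dataclass
class GroundTruth:
    records: list[TruthRecord] = field(default_factory=list)
    lineage_term_roots: dict[str, str] = field(default_factory=dict)

    def lineage_map(self) -> dict[str, set[str]]:
        """Lineage -> root-term-id sets, as consumed by coverage/motif modules."""
        return {lin: {tid} for lin, tid in self.lineage_term_roots.items()}


def generate_ontology(n_lineages: int, depth: int, branching: int, seed: int,
                      diamond_fraction: float = 0.0,
                      lineage_labels: Optional[tuple[str, ...]] = None) -> Ontology:
    """Rooted DAG: one ``branching``-ary subtree of ``depth`` levels per lineage.

    ``diamond_fraction`` of non-root subtree nodes receive one extra is_a
    parent drawn from another lineage, creating cross-lineage multi-parent
    diamonds. Without diamonds the node count is the closed form
    ``1 + n_lineages * sum(branching**l for l in range(depth))``.
    """
    if n_lineages < 1 or depth < 1:
        raise ValueError("need n_lineages >= 1 and depth >= 1")
    rng = np.random.default_rng(seed)
    labels = lineage_labels or tuple(f"L{i + 1}" for i in range(n_lineages))
    if len(labels) != n_lineages:
        raise ValueError("lineage_labels length mismatch")
    terms = {"SYN:ROOT": OntologyTerm("SYN:ROOT", label="cell")}
    edges: list[tuple[str, str]] = []
    serial = 0
    per_lineage_nodes: dict[str, list[str]] = {}
    for lin in labels:
        lin_root = f"SYN:{lin}:0"
        terms[lin_root] = OntologyTerm(lin_root, label=lineage_root_word(lin))
        edges.append((lin_root, "SYN:ROOT"))
        level = [lin_root]
        nodes = [lin_root]
        for _ in range(depth - 1):
            nxt = []
            for parent in level:
                for _ in range(branching):
                    serial += 1
                    tid = f"SYN:{lin}:{serial}"
                    terms[tid] = OntologyTerm(
                        tid, label=f"{lineage_root_word(lin)} type {serial}",
                        synonyms=[f"{lin} subtype {serial}"])
                    edges.append((tid, parent))
                    nxt.append(tid)
            level = nxt
            nodes.extend(level)
        per_lineage_nodes[lin] = nodes
    if diamond_fraction > 0 and n_lineages > 1:
        for lin in labels:
            candidates = per_lineage_nodes[lin][1:]  # skip the lineage root
            for tid in candidates:
                if rng.random() < diamond_fraction:
                    other = labels[rng.integers(len(labels))]
                    if other == lin:
                        continue
                    extra_parent = per_lineage_nodes[other][
                        rng.integers(len(per_lineage_nodes[other]))]
                    edges.append((tid, extra_parent))
    return Ontology(terms, edges, root_id="SYN:ROOT")


def generate_name(lineage: str, config: GeneratorConfig,
                  rng: np.random.Generator) -> tuple[str, list[tuple[int, int, str]]]:
    """Compose a cell name; returns (name, ground-truth motif char spans).

    Each motif slot is filled independently with its configured
    ``(lineage, motif_type)`` prevalence, drawing a word uniformly from that
    type's vocabulary; the lineage root word is appended last and recorded
    as a ``root`` motif span.
    """
    if lineage not in config.lineage_roots:
        raise ValueError(f"unknown lineage {lineage!r}")
    words: list[tuple[str, str]] = []  # (word, motif_type)
    for motif_type in NAME_MOTIF_ORDER:
        p = config.prevalence(lineage, motif_type)
        if p > 0 and rng.random() < p:
            vocab = MOTIF_VOCAB[motif_type]
            words.append((vocab[rng.integers(len(vocab))], motif_type))
    words.append((lineage_root_word(lineage), "root"))
    name_parts: list[str] = []
    spans: list[tuple[int, int, str]] = []
    pos = 0
    for word, motif_type in words:
        if name_parts:
            pos += 1  # single space separator
        spans.append((pos, pos + len(word), motif_type))
        name_parts.append(word)
        pos += len(word)
    return " ".join(name_parts), spans


_SENTENCE_TEMPLATES = (
    ("We observed ", " in these samples."),
    ("The cluster contained ", " at high frequency."),
    ("Staining revealed ", " near the lesion."),
    ("Profiling identified ", " in both donors."),
)


def generate_corpus(config: GeneratorConfig,
                    ontology: Optional[Ontology] = None
                    ) -> tuple[AnnotatedCorpus, GroundTruth]:
    """Generate an annotated corpus plus aligned ground truth.

    The output always passes :func:`~cytotext.corpus_model.validate_corpus`
    with zero violations: annotation spans land in distinct sentences, vague
    annotations carry no links, and every identifier resolves in the
    (possibly co-generated) ontology.
    """
    rng = np.random.default_rng(config.seed)
    if ontology is None:
        ontology = generate_ontology(
            len(config.lineage_roots), config.ontology_depth,
            config.ontology_branching, seed=config.seed,
            lineage_labels=tuple(config.lineage_roots))
    # term pools per lineage: lineage subtree nodes
    from .corpus_model import ancestors as _ancestors
    lineage_term_roots = {lin: f"SYN:{lin}:0" for lin in config.lineage_roots}
    lineage_pool: dict[str, list[str]] = {lin: [] for lin in config.lineage_roots}
    for tid in sorted(ontology.terms):
        anc = _ancestors(ontology, tid) | {tid}
        for lin, lin_root in lineage_term_roots.items():
            if lin_root in anc:
                lineage_pool[lin].append(tid)
    truth = GroundTruth(lineage_term_roots=lineage_term_roots)
    passages: list[Passage] = []
    mix = np.asarray(config.entity_type_mix, dtype=float)
    lo, hi = config.annotations_per_passage
    for p_idx in range(config.n_passages):
        article = p_idx // max(config.passages_per_article, 1)
        n_ann = int(rng.integers(lo, hi + 1))
        text_parts: list[str] = []
        annotations: list[CellAnnotation] = []
        offset = 0
        records: list[TruthRecord] = []
        for a_idx in range(n_ann):
            entity_type = ("cell_phenotype", "heterogeneous", "vague")[
                int(rng.choice(3, p=mix))]
            lineage = config.lineage_roots[int(rng.integers(len(config.lineage_roots)))]
            coordination = (entity_type != "vague"
                            and rng.random() < config.multi_id_fraction)
            name, motif_spans = generate_name(lineage, config, rng)
            lineages = (lineage,)
            if coordination:
                others = [l for l in config.lineage_roots if l != lineage] or [lineage]
                other = others[int(rng.integers(len(others)))]
                extra = lineage_root_word(other)
                motif_spans = list(motif_spans)
                joiner = " and "
                motif_spans.append((len(name) + len(joiner),
                                    len(name) + len(joiner) + len(extra), "root"))
                name = name + joiner + extra
                lineages = (lineage, other)
            if entity_type == "vague":
                name = name + " populations"
                links: list[OntologyLink] = []
                term_ids: tuple[str, ...] = ()
                quals: tuple[str, ...] = ()
            elif rng.random() < config.unlinked_fraction:
                links, term_ids, quals = [], (), ()
            else:
                ids = []
                for lin in lineages:
                    pool = lineage_pool[lin]
                    ids.append(pool[int(rng.integers(len(pool)))])
                qual = ("exact" if rng.random() < config.exact_link_fraction
                        else "related")
                links = [OntologyLink(t, qual) for t in ids]
                term_ids = tuple(ids)
                quals = tuple(qual for _ in ids)
            prefix, suffix = _SENTENCE_TEMPLATES[int(rng.integers(len(_SENTENCE_TEMPLATES)))]
            if text_parts:
                offset += 1  # joining space
            start = offset + len(prefix)
            sentence = prefix + name + suffix
            annotations.append(CellAnnotation(
                span=Span(start, start + len(name), name),
                entity_type=entity_type,
                links=links,
                annotator_id="A",
                ann_id=f"p{p_idx}a{a_idx}",
            ))
            records.append(TruthRecord(
                passage_index=p_idx, annotation_index=a_idx,
                entity_type=entity_type, term_ids=term_ids, qualifiers=quals,
                lineages=lineages,
                motif_spans=tuple(motif_spans),
                coordination=coordination,
            ))
            text_parts.append(sentence)
            offset += len(sentence)
        passages.append(Passage(
            doc_id=f"DOC{article:05d}",
            passage_type=_PASSAGE_TYPES[int(rng.integers(len(_PASSAGE_TYPES)))],
            text=" ".join(text_parts),
            year=int(rng.integers(2019, 2025)),
            journal=_JOURNALS[int(rng.integers(len(_JOURNALS)))],
            mesh_clusters={_MESH_CLUSTERS[int(rng.integers(len(_MESH_CLUSTERS)))]},
            annotations=annotations,
        ))
        truth.records.extend(records)
    corpus = AnnotatedCorpus(passages=passages, provenance=f"synthetic seed={config.seed}")
    return corpus, truth


def perturb_annotations(corpus: AnnotatedCorpus, drop_p: float, boundary_p: float,
                        relabel_id_p: float, seed: int,
                        ontology: Optional[Ontology] = None) -> AnnotatedCorpus:
    """Simulate a second independent annotator.

    Each annotation is independently dropped with probability ``drop_p``;
    surviving annotations have one span endpoint jittered by one character
    with probability ``boundary_p``, and each linked identifier replaced by
    a uniformly drawn sibling term with probability ``relabel_id_p``
    (requires ``ontology``).
    """
    for name, p in (("drop_p", drop_p), ("boundary_p", boundary_p),
                    ("relabel_id_p", relabel_id_p)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if relabel_id_p > 0 and ontology is None:
        raise ValueError("relabel_id_p > 0 requires an ontology")
    rng = np.random.default_rng(seed)
    out_passages: list[Passage] = []
    for passage in corpus.passages:
        new_anns: list[CellAnnotation] = []
        for ann in passage.annotations:
            if rng.random() < drop_p:
                continue
            start, end = ann.span.start, ann.span.end
            if rng.random() < boundary_p:
                moves = []
                if start + 1 < end:
                    moves.append(("start", 1))
                    moves.append(("end", -1))
                if start > 0:
                    moves.append(("start", -1))
                if end < len(passage.text):
                    moves.append(("end", 1))
                if moves:
                    which, delta = moves[int(rng.integers(len(moves)))]
                    if which == "start":
                        start += delta
                    else:
                        end += delta
            links = []
            for link in ann.links:
                term_id = link.term_id
                if relabel_id_p > 0 and rng.random() < relabel_id_p:
                    sibs = sorted(ontology.siblings(term_id))
                    if sibs:
                        term_id = sibs[int(rng.integers(len(sibs)))]
                links.append(OntologyLink(term_id, link.qualifier))
            new_anns.append(CellAnnotation(
                span=Span(start, end, passage.text[start:end]),
                entity_type=ann.entity_type,
                links=links,
                annotator_id="B",
                ann_id=ann.ann_id,
            ))
        out_passages.append(Passage(
            doc_id=passage.doc_id, passage_type=passage.passage_type,
            text=passage.text, year=passage.year, journal=passage.journal,
            mesh_clusters=set(passage.mesh_clusters), annotations=new_anns))
    return AnnotatedCorpus(passages=out_passages,
                           provenance=corpus.provenance + " | perturbed")


def generate_confidence_scores(n_pos: int, n_neg: int, separation: float,
                               seed: int) -> list[tuple[float, bool]]:
    """Linker confidence scores with controlled class separation.

    Scores are uniform on width-0.2 windows centred at ``0.5 +/- separation/2``
    (clipped to the unit interval), so the class means differ by
    ``separation`` and supports become disjoint once ``separation > 0.2``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one score per class")
    rng = np.random.default_rng(seed)
    half_width = 0.1

    def draw(n: int, center: float) -> np.ndarray:
        lo = center - half_width
        hi = center + half_width
        return np.clip(rng.uniform(lo, hi, size=n), 0.0, 1.0)

    pos = draw(n_pos, min(0.5 + separation / 2, 1.0 - half_width))
    neg = draw(n_neg, max(0.5 - separation / 2, half_width))
    scored = [(float(s), True) for s in pos] + [(float(s), False) for s in neg]
    return scored


def manual_motif_map(lineages: tuple[str, ...] = DEFAULT_LINEAGES
                     ) -> dict[tuple[str, ...], str]:
    """Exact lemma -> motif-type map covering the generator vocabularies.

    Keys are stemmed/casefolded to match the default lemmatizer, so manual
    matching alone fully recovers generated motif spans.
    """
    from .linking_eval import stem_plural

    mapping: dict[tuple[str, ...], str] = {}
    for motif_type, words in MOTIF_VOCAB.items():
        for word in words:
            mapping[(stem_plural(word.casefold()),)] = motif_type
    for lineage in lineages:
        mapping[(stem_plural(lineage_root_word(lineage)),)] = "root"
    mapping[("cell",)] = "root"
    return mapping


def classifier_training_data(n_per_word: int = 1) -> list[tuple[str, str]]:
    """(phrase, motif_type) examples from the generator vocabularies."""
    return [(word, motif_type)
            for motif_type, words in MOTIF_VOCAB.items()
            for word in words
            for _ in range(n_per_word)]


def expected_tree_size(n_lineages: int, depth: int, branching: int) -> int:
    """Closed-form node count of :func:`generate_ontology` without diamonds."""
    per_lineage = sum(branching ** level for level in range(depth))
    return 1 + n_lineages * per_lineage


def expected_drop_only_f1(drop_p: float) -> float:
    """Pooled strict-span F1 when one annotator copy drops each span w.p. d."""
    return 2.0 * (1.0 - drop_p) / (2.0 - drop_p)
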