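"""Core data model for annotated corpora and ontologies.

Character offsets are 0-based, half-open, over the passage's decoded text.
Only ``is_a`` edges are traversed for ancestor and depth queries; depth is
the length of the *shortest* ``is_a`` path from the root (configurable to
longest via :func:`term_depth`).
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional
from xml.etree import ElementTree as ET

import networkx as nx

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("cell_phenotype", "heterogeneous", "vague")
PASSAGE_TYPES = (
    "title",
    "abstract",
    "paragraph",
    "section_header",
    "caption",
    "table",
    "supplementary",
)
LINK_QUALIFIERS = ("exact", "related")


class CorpusValidationError(ValueError):
    """Raised when a corpus file violates a structural invariant."""


class OntologyLookupError(KeyError):
    """Raised when a term id does not resolve in the loaded ontology."""


@dataclass(frozen=True)
class Span:
    """Half-open character interval within a passage."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span bounds ({self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class OntologyLink:
    term_id: str
    qualifier: str = "exact"

    def __post_init__(self) -> None:
        if self.qualifier not in LINK_QUALIFIERS:
            raise ValueError(f"unknown link qualifier {self.qualifier!r}")


@dataclass
class CellAnnotation:
    span: Span
    entity_type: str
    links: list[OntologyLink] = field(default_factory=list)
    annotator_id: str = ""
    ann_id: str = ""

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")

    @property
    def exact_ids(self) -> frozenset[str]:
        return frozenset(l.term_id for l in self.links if l.qualifier == "exact")

    @property
    def all_ids(self) -> frozenset[str]:
        return frozenset(l.term_id for l in self.links)


@dataclass
class Passage:
    doc_id: str
    passage_type: str
    text: str
    year: int = 0
    journal: str = ""
    mesh_clusters: set[str] = field(default_factory=set)
    annotations: list[CellAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passage_type not in PASSAGE_TYPES:
            raise ValueError(f"unknown passage type {self.passage_type!r}")


@dataclass
class AnnotatedCorpus:
    passages: list[Passage] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[Passage]:
        return iter(self.passages)

    def __len__(self) -> int:
        return len(self.passages)

    def annotations(self) -> Iterator[tuple[int, Passage, CellAnnotation]]:
        """Yield (passage index, passage, annotation) triples."""
        for i, passage in enumerate(self.passages):
            for ann in passage.annotations:
                yield i, passage, ann


@dataclass
class OntologyTerm:
    term_id: str
    label: str = ""
    synonyms: list[str] = field(default_factory=list)
    obsolete: bool = False
    replaced_by: Optional[str] = None


class Ontology:
    """A rooted DAG of terms connected by ``is_a`` edges.

    Parameters
    ----------
    terms
        Mapping from term id to :class:`OntologyTerm`.
    edges
        ``(child_id, parent_id)`` pairs, each an ``is_a`` assertion.
    root_id
        The unique top concept. If ``None``, inferred as the single term
        with no parents.
    """

    def __init__(
        self,
        terms: dict[str, OntologyTerm],
        edges: Iterable[tuple[str, str]],
        root_id: Optional[str] = None,
    ) -> None:
        self.terms = dict(terms)
        self.graph = nx.DiGraph()  # edge child -> parent
        self.graph.add_nodes_from(self.terms)
        for child, parent in edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyLookupError(f"edge references unknown term ({child}, {parent})")
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("is_a graph contains a cycle")
        if root_id is None:
            roots = [t for t in self.terms if self.graph.out_degree(t) == 0
                     and not self.terms[t].obsolete]
            if len(roots) != 1:
                raise ValueError(f"cannot infer a unique root (found {len(roots)})")
            root_id = roots[0]
        if root_id not in self.terms:
            raise OntologyLookupError(root_id)
        self.root_id = root_id
        self._depth_cache: Optional[dict[str, int]] = None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> Optional[str]:
        """Resolve an id, following ``replaced_by`` for obsolete terms.

        Returns ``None`` when the id does not resolve at all.
        """
        term = self.terms.get(term_id)
        if term is None:
            return None
        if term.obsolete and term.replaced_by:
            logger.info("obsolete term %s mapped to replacement %s", term_id, term.replaced_by)
            return self.resolve(term.replaced_by)
        return term_id

    def parents(self, term_id: str) -> set[str]:
        if term_id not in self.terms:
            raise OntologyLookupError(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        if term_id not in self.terms:
            raise OntologyLookupError(term_id)
        return set(self.graph.predecessors(term_id))

    def siblings(self, term_id: str) -> set[str]:
        """Terms sharing at least one parent with ``term_id`` (excluded itself)."""
        sibs: set[str] = set()
        for parent in self.parents(term_id):
            sibs |= self.children(parent)
        sibs.discard(term_id)
        return sibs

    def _depths(self) -> dict[str, int]:
        # single BFS over reversed (parent -> child) edges from the root,
        # skipping edges out of obsolete terms
        if self._depth_cache is None:
            depths = {self.root_id: 0}
            queue = deque([self.root_id])
            while queue:
                node = queue.popleft()
                for child in self.graph.predecessors(node):
                    if self.terms[child].obsolete:
                        continue
                    if child not in depths:
                        depths[child] = depths[node] + 1
                        queue.append(child)
            self._depth_cache = depths
        return self._depth_cache


def term_depth(ontology: Ontology, term_id: str, longest: bool = False) -> Optional[int]:
    """Length of the shortest (default) or longest ``is_a`` path from the root.

    Returns ``None`` for terms unreachable from the root; such terms are
    excluded from depth statistics.
    """
    if term_id not in ontology.terms:
        raise OntologyLookupError(term_id)
    if not longest:
        return ontology._depths().get(term_id)
    # longest path in a DAG: dynamic programming over parents
    memo: dict[str, Optional[int]] = {}

    def longest_to_root(t: str) -> Optional[int]:
        if t == ontology.root_id:
            return 0
        if t in memo:
            return memo[t]
        best: Optional[int] = None
        for parent in ontology.graph.successors(t):
            d = longest_to_root(parent)
            if d is not None and (best is None or d + 1 > best):
                best = d + 1
        memo[t] = best
        return best

    return longest_to_root(term_id)


def ancestors(ontology: Ontology, term_id: str) -> set[str]:
    """Transitive ``is_a`` closure of ``term_id``, excluding the term itself."""
    if term_id not in ontology.terms:
        raise OntologyLookupError(term_id)
    return set(nx.descendants(ontology.graph, term_id))


@dataclass(frozen=True)
class Violation:
    kind: str  # vague_linked | illegal_overlap | span_mismatch | span_bounds | unresolved_id
    passage_index: int
    doc_id: str
    detail: str


def validate_corpus(corpus: AnnotatedCorpus, ontology: Optional[Ontology] = None) -> list[Violation]:
    """Check every guideline invariant; violations are data, not exceptions.

    An empty result certifies guideline conformance: no vague annotation
    carries links, annotation overlap occurs only where a vague span
    strictly contains a non-vague span, every span matches its passage
    substring, and (when an ontology is supplied) every link resolves.
    """
    violations: list[Violation] = []
    for i, passage in enumerate(corpus.passages):
        n = len(passage.text)
        for ann in passage.annotations:
            sp = ann.span
            if sp.end > n:
                violations.append(Violation("span_bounds", i, passage.doc_id,
                                            f"span ({sp.start},{sp.end}) outside passage of length {n}"))
            elif passage.text[sp.start:sp.end] != sp.text:
                violations.append(Violation("span_mismatch", i, passage.doc_id,
                                            f"span text {sp.text!r} != passage slice"))
            if ann.entity_type == "vague" and ann.links:
                violations.append(Violation("vague_linked", i, passage.doc_id,
                                            f"vague annotation {sp.text!r} carries links"))
            if ontology is not None:
                for link in ann.links:
                    if ontology.resolve(link.term_id) is None:
                        violations.append(Violation("unresolved_id", i, passage.doc_id,
                                                    f"unresolved identifier {link.term_id}"))
        anns = passage.annotations
        for a in range(len(anns)):
            for b in range(a + 1, len(anns)):
                x, y = anns[a], anns[b]
                if not x.span.overlaps(y.span):
                    continue
                legal = (
                    (x.entity_type == "vague" and y.entity_type != "vague"
                     and x.span.contains(y.span) and x.span != y.span)
                    or (y.entity_type == "vague" and x.entity_type != "vague"
                        and y.span.contains(x.span) and x.span != y.span)
                )
                if not legal:
                    violations.append(Violation("illegal_overlap", i, passage.doc_id,
                                                f"{x.span.text!r} overlaps {y.span.text!r}"))
    return violations


# ---------------------------------------------------------------------------
# BioC XML I/O
#
# Canonical infon keys: passage "type"/"year"/"journal"/"mesh_clusters";
# annotation "type", "identifier" (semicolon-joined), "qualifier"
# (semicolon-joined, parallel to identifiers), "annotator".
# Annotation offsets are absolute document offsets (BioC convention);
# consecutive passages of a document are separated by one newline.
# ---------------------------------------------------------------------------

def write_bioc(corpus: AnnotatedCorpus, path: str) -> None:
    """Serialize to canonical BioC XML (deterministic byte output)."""
    root = ET.Element("collection")
    ET.SubElement(root, "source").text = "cytotext"
    ET.SubElement(root, "key").text = corpus.provenance or ""
    # preserve passage order; group consecutive passages with equal doc_id
    doc_el = None
    current_doc = object()
    offset = 0
    ann_serial = 0
    for passage in corpus.passages:
        if passage.doc_id != current_doc:
            doc_el = ET.SubElement(root, "document")
            ET.SubElement(doc_el, "id").text = passage.doc_id
            current_doc = passage.doc_id
            offset = 0
        p_el = ET.SubElement(doc_el, "passage")
        _infon(p_el, "type", passage.passage_type)
        _infon(p_el, "year", str(passage.year))
        _infon(p_el, "journal", passage.journal)
        _infon(p_el, "mesh_clusters", ";".join(sorted(passage.mesh_clusters)))
        ET.SubElement(p_el, "offset").text = str(offset)
        ET.SubElement(p_el, "text").text = passage.text
        for ann in passage.annotations:
            ann_serial += 1
            a_el = ET.SubElement(p_el, "annotation", id=ann.ann_id or str(ann_serial))
            _infon(a_el, "type", ann.entity_type)
            _infon(a_el, "identifier", ";".join(l.term_id for l in ann.links))
            _infon(a_el, "qualifier", ";".join(l.qualifier for l in ann.links))
            _infon(a_el, "annotator", ann.annotator_id)
            ET.SubElement(a_el, "location",
                          offset=str(offset + ann.span.start),
                          length=str(ann.span.end - ann.span.start))
            ET.SubElement(a_el, "text").text = ann.span.text
        offset += len(passage.text) + 1
    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    tree.write(path, encoding="unicode", xml_declaration=True)


def _infon(parent: ET.Element, key: str, value: str) -> None:
    el = ET.SubElement(parent, "infon", key=key)
    el.text = value


def read_bioc(path: str) -> AnnotatedCorpus:
    """Parse a BioC XML collection into an :class:`AnnotatedCorpus`.

    Round-trips with :func:`write_bioc` bit-identically for canonical
    output. Malformed XML raises :class:`xml.etree.ElementTree.ParseError`
    naming the offending line; spans outside their passage raise
    :class:`CorpusValidationError`.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    key_el = root.find("key")
    provenance = (key_el.text or "") if key_el is not None else ""
    passages: list[Passage] = []
    for doc_el in root.findall("document"):
        doc_id = doc_el.findtext("id", default="")
        for p_el in doc_el.findall("passage"):
            infons = {el.get("key"): (el.text or "") for el in p_el.findall("infon")}
            offset = int(p_el.findtext("offset", default="0"))
            text = p_el.findtext("text", default="") or ""
            mesh = set(v for v in infons.get("mesh_clusters", "").split(";") if v)
            passage = Passage(
                doc_id=doc_id,
                passage_type=infons.get("type", "paragraph"),
                text=text,
                year=int(infons.get("year", "0") or 0),
                journal=infons.get("journal", ""),
                mesh_clusters=mesh,
            )
            for a_el in p_el.findall("annotation"):
                a_infons = {el.get("key"): (el.text or "") for el in a_el.findall("infon")}
                loc = a_el.find("location")
                start = int(loc.get("offset")) - offset
                length = int(loc.get("length"))
                ann_text = a_el.findtext("text", default="") or ""
                if start < 0 or start + length > len(text):
                    raise CorpusValidationError(
                        f"annotation {a_el.get('id')!r} span ({start},{start + length}) "
                        f"outside passage of length {len(text)}")
                ids = [v for v in a_infons.get("identifier", "").split(";") if v]
                quals = [v for v in a_infons.get("qualifier", "").split(";") if v]
                if len(quals) < len(ids):
                    quals = quals + ["exact"] * (len(ids) - len(quals))
                links = [OntologyLink(t, q) for t, q in zip(ids, quals)]
                passage.annotations.append(CellAnnotation(
                    span=Span(start, start + length, ann_text),
                    entity_type=a_infons.get("type", "cell_phenotype"),
                    links=links,
                    annotator_id=a_infons.get("annotator", ""),
                    ann_id=a_el.get("id", ""),
                ))
            passages.append(passage)
    return AnnotatedCorpus(passages=passages, provenance=provenance)


# ---------------------------------------------------------------------------
# Ontology loaders
# ---------------------------------------------------------------------------

def read_obograph_json(path: str, root_id: Optional[str] = None) -> Ontology:
    """Load the OBO-graph JSON subset: nodes with lbl/meta, edges with pred 'is_a'."""
    with open(path) as fh:
        data = json.load(fh)
    graph = data["graphs"][0] if "graphs" in data else data
    terms: dict[str, OntologyTerm] = {}
    for node in graph.get("nodes", []):
        meta = node.get("meta", {}) or {}
        synonyms = [s.get("val", "") for s in meta.get("synonyms", [])]
        replaced = meta.get("basicPropertyValues", [])
        replaced_by = None
        for bp in replaced:
            if bp.get("pred", "").endswith("replaced_by") or bp.get("pred") == "replaced_by":
                replaced_by = bp.get("val")
        terms[node["id"]] = OntologyTerm(
            term_id=node["id"],
            label=node.get("lbl", ""),
            synonyms=[s for s in synonyms if s],
            obsolete=bool(meta.get("deprecated", False)),
            replaced_by=replaced_by,
        )
    edges = [(e["sub"], e["obj"]) for e in graph.get("edges", [])
             if e.get("pred") in ("is_a", "subClassOf")]
    return Ontology(terms, edges, root_id=root_id)


def read_ontology_tsv(path: str, root_id: Optional[str] = None) -> Ontology:
    """Load a 3-column TSV edge list: child, parent, child-label.

    The root is listed with an empty parent column.
    """
    terms: dict[str, OntologyTerm] = {}
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            child = parts[0]
            parent = parts[1] if len(parts) > 1 else ""
            label = parts[2] if len(parts) > 2 else ""
            if child not in terms:
                terms[child] = OntologyTerm(child, label=label or child)
            elif label:
                terms[child].label = label
            if parent:
                if parent not in terms:
                    terms[parent] = OntologyTerm(parent, label=parent)
                edges.append((child, parent))
    return Ontology(terms, edges, root_id=root_id)


def write_obograph_json(ontology: Ontology, path: str) -> None:
    nodes = []
    for term in ontology.terms.values():
        node: dict = {"id": term.term_id, "lbl": term.label}
        meta: dict = {}
        if term.synonyms:
            meta["synonyms"] = [{"val": s} for s in term.synonyms]
        if term.obsolete:
            meta["deprecated"] = True
        if term.replaced_by:
            meta["basicPropertyValues"] = [{"pred": "replaced_by", "val": term.replaced_by}]
        if meta:
            node["meta"] = meta
        nodes.append(node)
    edges = [{"sub": c, "pred": "is_a", "obj": p} for c, p in sorted(ontology.graph.edges())]
    with open(path, "w") as fh:
        json.dump({"graphs": [{"nodes": nodes, "edges": edges}]}, fh, indent=1, sort_keys=True)
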