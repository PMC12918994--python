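import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytotext import corpus_model as cm
from cytotext import motif_analysis as ma
from cytotext import synthetic_data as sd
from cytotext.linking_eval import HashedNGramEmbedder


def binom_oracle(k, n, p0):
    """Enumerate all 2^n outcome sequences; sum sequence probabilities whose
    success-count point probability is <= that of the observed k."""
    pmf = [0.0] * (n + 1)
    for bits in itertools.product((0, 1), repeat=n):
        prob = math.prod(p0 if b else 1 - p0 for b in bits)
        pmf[sum(bits)] += prob
    cut = pmf[k] * (1 + 1e-9)
    return min(1.0, sum(p for p in pmf if p <= cut))


def fisher_oracle(a, b, c, d):
    """Hypergeometric enumeration from binomial coefficients only."""
    row1, row2 = a + b, c + d
    col1 = a + c
    total = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == total:
        return 1.0
    denom = math.comb(total, col1)
    probs = {}
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        probs[x] = math.comb(row1, x) * math.comb(row2, col1 - x) / denom
    cut = probs[a] * (1 + 1e-9)
    return min(1.0, sum(p for p in probs.values() if p <= cut))


class TestMotifVocabulary:
    def test_exactly_fourteen_types(self):
        assert len(ma.MOTIF_TYPES) == 14
        assert len(set(ma.MOTIF_TYPES)) == 14

    def test_expected_members(self):
        assert set(ma.MOTIF_TYPES) == {
            "root", "anatomical_context", "lineage", "molecular_signature",
            "appearance", "functional_role", "developmental_stage", "state",
            "variant", "molecular_signaling", "disease", "eponym", "stimulus",
            "species_sex"}

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            ma.MotifSpan(0, 1, "fifteenth_type", "manual")


class TestExtractCandidates:
    def test_full_enumeration(self):
        cands = ma.extract_candidates(["exhausted", "cd8", "t"], (), set())
        assert len(cands) == 6
        assert set(cands) == {(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)}

    def test_stopword_endpoint_rule(self):
        cands = ma.extract_candidates(["t", "and", "nk"], (), {"and"})
        assert set(cands) == {(0, 1), (2, 3), (0, 3)}

    def test_manual_span_blocks_everything(self):
        assert ma.extract_candidates(["a", "b"], [(0, 2)], set()) == []

    def test_max_length_three(self):
        tokens = ["a"] * 8
        cands = ma.extract_candidates(tokens, (), set())
        assert max(j - i for i, j in cands) == 3

    def test_bad_manual_span(self):
        with pytest.raises(ValueError):
            ma.extract_candidates(["a"], [(0, 5)], set())


class TestApplyManualMap:
    def test_single_match(self):
        spans = ma.apply_manual_map(
            ["regulatory", "t", "cell"], {("regulatory",): "functional_role"})
        assert len(spans) == 1
        assert spans[0] == ma.MotifSpan(0, 1, "functional_role", "manual")

    def test_longest_match_wins(self):
        mapping = {("cardiac",): "anatomical_context",
                   ("cardiac", "muscle"): "anatomical_context"}
        spans = ma.apply_manual_map(["cardiac", "muscle", "cell"], mapping)
        assert spans[0].end == 2

    def test_empty_map(self):
        assert ma.apply_manual_map(["a", "b"], {}) == []

    def test_non_overlapping(self):
        mapping = {("a",): "state", ("a", "b"): "disease", ("b",): "variant"}
        spans = ma.apply_manual_map(["a", "b", "a"], mapping)
        assert [(s.start, s.end) for s in spans] == [(0, 2), (2, 3)]
        for s1, s2 in itertools.combinations(spans, 2):
            assert not s1.overlaps(s2)


@pytest.fixture(scope="module")
def embedder():
    return HashedNGramEmbedder(dim=256)


@pytest.fixture(scope="module")
def trained_classifier(embedder):
    return ma.train_motif_classifier(sd.classifier_training_data(), embedder, seed=0)


class TestClassifier:
    def test_training_accuracy_on_separable_data(self, trained_classifier):
        data = sd.classifier_training_data()
        correct = sum(trained_classifier.predict_with_margin(text)[0] == motif
                      for text, motif in data)
        assert correct / len(data) == 1.0

    def test_probabilities_sum_to_one(self, trained_classifier):
        probs = trained_classifier.predict_proba("naive hepatic cell")
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_single_class_rejected(self, embedder):
        with pytest.raises(ValueError):
            ma.train_motif_classifier([("a", "state"), ("b", "state")], embedder)

    def test_cv_protocol_accuracy(self, embedder):
        data = sd.classifier_training_data(n_per_word=3)
        acc = ma.classifier_cv_accuracy(data, embedder, n_splits=10, n_repeats=5)
        assert acc > 0.9  # separable by construction


class TestAssignMotifs:
    def test_manual_only(self, trained_classifier):
        spans = ma.assign_motifs(["regulatory", "alphacyte"],
                                 {("regulatory",): "functional_role",
                                  ("alphacyte",): "root"})
        assert [s.source for s in spans] == ["manual", "manual"]

    def test_increasing_margin_places_low_margin_first(self):
        class FakeClassifier:
            def predict_with_margin(self, phrase):
                margins = {"a": 0.1, "b": 0.6, "a b": 0.3}
                return "state", margins[phrase]

        spans = ma.assign_motifs(["a", "b"], {}, FakeClassifier(), stopwords=set())
        # candidates: a (0.1), b (0.6), "a b" (0.3); a placed first, then
        # "a b" overlaps it, then b still fits
        assert {(s.start, s.end) for s in spans} == {(0, 1), (1, 2)}
        by_span = {(s.start, s.end): s for s in spans}
        assert by_span[(0, 1)].margin == pytest.approx(0.1)

    def test_decreasing_margin_order(self):
        class FakeClassifier:
            def predict_with_margin(self, phrase):
                margins = {"a": 0.1, "b": 0.2, "a b": 0.9}
                return "disease", margins[phrase]

        spans = ma.assign_motifs(["a", "b"], {}, FakeClassifier(), stopwords=set(),
                                 margin_order="decreasing")
        assert [(s.start, s.end) for s in spans] == [(0, 2)]

    def test_placed_spans_pairwise_disjoint(self, trained_classifier):
        rng = np.random.default_rng(0)
        vocab_words = [w for ws in sd.MOTIF_VOCAB.values() for w in ws]
        for _ in range(30):
            tokens = [vocab_words[i].lower()
                      for i in rng.integers(0, len(vocab_words), size=5)]
            spans = ma.assign_motifs(tokens, sd.manual_motif_map(),
                                     trained_classifier)
            for s1, s2 in itertools.combinations(spans, 2):
                assert not s1.overlaps(s2)


class TestAssignLineages:
    @pytest.fixture
    def lineage_onto(self):
        terms = {t: cm.OntologyTerm(t) for t in ("R", "A", "B", "AB", "X", "UA", "UAB")}
        edges = [("A", "R"), ("B", "R"), ("AB", "A"), ("AB", "B"),
                 ("X", "R"), ("UA", "A"), ("UAB", "AB")]
        onto = cm.Ontology(terms, edges, root_id="R")
        return onto, {"La": {"A"}, "Lb": {"B"}}

    def test_single_lineage(self, lineage_onto):
        onto, lmap = lineage_onto
        assert ma.assign_lineages(["UA"], onto, lmap) == {"La": 1.0}

    def test_equal_split_across_lineages(self, lineage_onto):
        onto, lmap = lineage_onto
        weights = ma.assign_lineages(["UAB"], onto, lmap)
        assert weights == {"La": 0.5, "Lb": 0.5}

    def test_two_links_fractional(self, lineage_onto):
        onto, lmap = lineage_onto
        weights = ma.assign_lineages(["UA", "UAB"], onto, lmap)
        assert weights["La"] == pytest.approx(0.75)
        assert weights["Lb"] == pytest.approx(0.25)

    def test_no_lineage_hit_excluded(self, lineage_onto):
        onto, lmap = lineage_onto
        assert ma.assign_lineages(["X"], onto, lmap) == {}

    def test_weights_sum_to_one(self, small_corpus, small_ontology):
        corpus, truth = small_corpus
        lmap = truth.lineage_map()
        for _, _, ann in corpus.annotations():
            if not ann.links:
                continue
            weights = ma.assign_lineages(ann.links, small_ontology, lmap)
            if weights:
                assert sum(weights.values()) == pytest.approx(1.0)


class TestPrevalenceTable:
    def test_motif_everywhere(self):
        records = [({"La": 1.0}, {"state", "root"}), ({"Lb": 1.0}, {"state"})]
        table = ma.prevalence_table(records)
        assert table.prevalence("La", "state") == 1.0
        assert table.prevalence("Lb", "state") == 1.0
        assert table.prevalence(ma.ALL_LINEAGES, "state") == 1.0

    def test_weighted_ratio(self):
        records = [({"La": 1.0}, {"state"}), ({"La": 0.5, "Lb": 0.5}, set())]
        table = ma.prevalence_table(records)
        assert table.prevalence("La", "state") == pytest.approx(1 / 1.5)

    def test_zero_weight_records_skipped(self):
        table = ma.prevalence_table([({}, {"state"})])
        assert table.den == {}

    def test_recovery_2000_names(self, trained_classifier):
        # configured prevalence recovered within the 99% binomial band
        p_true = 0.3
        config = sd.GeneratorConfig(
            seed=41, motif_prevalence={("alpha", "state"): p_true,
                                       ("alpha", "anatomical_context"): 0.5})
        rng = np.random.default_rng(41)
        manual = sd.manual_motif_map()
        n = 2_000
        hits = 0
        for _ in range(n):
            name, _ = sd.generate_name("alpha", config, rng)
            tokens = ma.default_lemmatize(name)
            spans = ma.assign_motifs(tokens, manual, trained_classifier)
            hits += any(s.motif_type == "state" for s in spans)
        band = 2.576 * math.sqrt(p_true * (1 - p_true) / n)
        assert abs(hits / n - p_true) < band


class TestExactTests:
    def test_binomial_mode_is_one(self):
        assert ma.binom_test_exact(5, 10, 0.5) == pytest.approx(1.0)

    def test_binomial_symmetric_tail(self):
        assert ma.binom_test_exact(0, 10, 0.5) == pytest.approx(2 / 1024)

    def test_binomial_exhaustive_oracle(self):
        for n in range(1, 13):
            for p0 in (0.1, 0.5, 0.9):
                for k in range(n + 1):
                    assert ma.binom_test_exact(k, n, p0) == pytest.approx(
                        binom_oracle(k, n, p0), abs=1e-12), (k, n, p0)

    def test_binomial_invalid(self):
        with pytest.raises(ValueError):
            ma.binom_test_exact(5, 4, 0.5)
        with pytest.raises(ValueError):
            ma.binom_test_exact(1, 4, 0.0)

    def test_fisher_hand_values(self):
        assert ma.fisher_exact(5, 0, 0, 5) == pytest.approx(2 / 252)
        assert ma.fisher_exact(1, 1, 1, 1) == pytest.approx(1.0)

    def test_fisher_degenerate_margins(self):
        assert ma.fisher_exact(0, 0, 3, 4) == 1.0

    def test_fisher_exhaustive_oracle_small_margins(self):
        for a in range(7):
            for b in range(7 - a):
                for c in range(7 - a):
                    for d in range(7 - b):
                        if (a + b) and (c + d) and (a + c) and (b + d):
                            assert ma.fisher_exact(a, b, c, d) == pytest.approx(
                                fisher_oracle(a, b, c, d), abs=1e-12), (a, b, c, d)

    def test_bh_step_up(self):
        assert ma.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_bh_single(self):
        assert ma.bh_adjust([0.3]) == [0.3]

    def test_bh_preserves_input_order(self):
        q = ma.bh_adjust([0.04, 0.01])
        assert q[1] <= q[0]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_bh_q_at_least_p_and_rank_monotone(self, ps):
        qs = ma.bh_adjust(ps)
        for p, q in zip(ps, qs):
            assert q >= p - 1e-12
            assert q <= 1.0
        order = np.argsort(ps)
        sorted_qs = [qs[i] for i in order]
        assert sorted_qs == sorted(sorted_qs)


class TestComparePrevalence:
    def test_table_vs_itself_reference_nothing_significant(self):
        rng = np.random.default_rng(50)
        records = []
        for _ in range(300):
            lin = ("La", "Lb")[rng.integers(2)]
            present = {"state"} if rng.random() < 0.3 else set()
            records.append(({lin: 1.0}, present))
        table = ma.prevalence_table(records)
        results = ma.compare_prevalence(table, reference=table)
        assert all(not r.significant for r in results)

    def test_shift_detected_with_direction(self):
        rng = np.random.default_rng(51)
        records = []
        for _ in range(400):
            records.append(({"La": 1.0}, {"state"} if rng.random() < 0.6 else set()))
            records.append(({"Lb": 1.0}, {"state"} if rng.random() < 0.2 else set()))
        table = ma.prevalence_table(records)
        results = {(r.lineage, r.motif_type): r for r in ma.compare_prevalence(table)}
        assert results[("La", "state")].significant
        assert results[("La", "state")].direction == "higher"
        assert results[("Lb", "state")].significant
        assert results[("Lb", "state")].direction == "lower"

    def test_reference_mode_adds_fisher_rows(self):
        rng = np.random.default_rng(52)
        def build(p):
            return ma.prevalence_table(
                [({"La": 1.0}, {"disease"} if rng.random() < p else set())
                 for _ in range(300)])
        results = ma.compare_prevalence(build(0.5), reference=build(0.05))
        fisher_rows = [r for r in results if r.test == "fisher"]
        assert fisher_rows
        row = next(r for r in fisher_rows if r.motif_type == "disease")
        assert row.significant and row.direction == "higher"

    def test_q_ge_p_and_significance_definition(self):
        rng = np.random.default_rng(53)
        records = [({"La": 1.0}, {"state"} if rng.random() < 0.4 else set())
                   for _ in range(100)]
        table = ma.prevalence_table(records)
        for r in ma.compare_prevalence(table):
            assert r.q_value >= r.p_value - 1e-12
            assert r.significant == (r.q_value < 0.01)


class TestEligibility:
    def test_scope_filters(self, small_ontology):
        config = sd.GeneratorConfig(seed=60, n_passages=100, multi_id_fraction=0.3,
                                    unlinked_fraction=0.2,
                                    entity_type_mix=(0.6, 0.2, 0.2))
        corpus, truth = sd.generate_corpus(config, small_ontology)
        kept = ma.eligible_annotations(corpus)
        assert kept
        for _, _, ann in kept:
            assert ann.entity_type != "vague"
            assert ann.links
            assert len(ann.all_ids) == 1

    def test_keyword_exclusion(self):
        p = cm.Passage(doc_id="D", passage_type="paragraph",
                       text="cultured alphacyte here")
        p.annotations.append(cm.CellAnnotation(
            span=cm.Span(0, 18, "cultured alphacyte"),
            entity_type="cell_phenotype", links=[cm.OntologyLink("A")]))
        assert ma.eligible_annotations(cm.AnnotatedCorpus([p])) == []


class TestEndToEnd:
    def test_injected_shift_detected(self, small_ontology, trained_classifier):
        prev = {(l, "molecular_signature"): 0.2 for l in sd.DEFAULT_LINEAGES}
        prev[("alpha", "molecular_signature")] = 0.5
        config = sd.GeneratorConfig(seed=61, n_passages=700,
                                    motif_prevalence=prev,
                                    entity_type_mix=(1.0, 0.0, 0.0),
                                    exact_link_fraction=1.0)
        corpus, truth = sd.generate_corpus(config, small_ontology)
        records = ma.label_corpus_motifs(
            corpus, small_ontology, truth.lineage_map(), sd.manual_motif_map(),
            classifier=trained_classifier)
        table = ma.prevalence_table([(w, p) for w, p, _ in records])
        results = {(r.lineage, r.motif_type): r
                   for r in ma.compare_prevalence(table)}
        hit = results[("alpha", "molecular_signature")]
        assert hit.significant and hit.direction == "higher"
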