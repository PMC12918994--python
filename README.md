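# cytotext

A toolkit for building and evaluating cell-population annotation corpora.
It covers the full computational methodology around a span-annotated,
ontology-linked literature corpus:

- **corpus_model** — data model for passages, span annotations with
  exact/related ontology links, and a DAG ontology with ancestor/depth
  queries; BioC XML reading/writing and guideline-invariant validation.
- **synthetic_data** — seeded generators for toy ontologies,
  motif-structured cell names, annotated corpora with aligned ground truth,
  dual-annotator perturbations, and linker confidence scores.
- **designed_sampler** — representative-yet-enriched passage selection by
  greedy KL-divergence minimization against a tempered, adjusted target
  feature distribution, with a per-article cap.
- **splitter** — train/validation/test partitioning (default 1/2, 1/6, 1/3)
  by hill climbing on a balance + per-subset-uniqueness objective.
- **agreement** — inter-annotator agreement in four strictness variants
  (strict span+id, strict span, strict id, approximate span), plus
  automated flagging of divergent links and uncovered subset-descriptor
  phrases.
- **ner_eval** — span-level scoring of any tagger's BioC predictions under
  exact/approximate spans and typed/merged labels (one-to-one matching,
  micro-averaged).
- **linking_eval** — embedding-based candidate retrieval against the
  ontology (pluggable embedder; a deterministic hashed character-trigram
  backend ships by default), single-link F1 with exact-only vs all-ids
  gold semantics, top-k recall, and novelty-detection ROC/AUROC.
- **coverage** — ontology coverage statistics: depth histograms, mean
  depth, normalized depth-distribution L1 distance, lineage counts.
- **motif_analysis** — labeling of the 14 compositional naming-motif types
  via a manual lemma map plus a margin-ordered logistic-regression
  classifier, fractional lineage assignment through the ontology, and
  exact binomial / Fisher prevalence tests under BH FDR control.

## Command line

A single `cytotext` entry point exposes the pipeline:

```bash
cytotext synth --seed 7 --n-passages 200 --out corpus.xml \
    --truth truth.json --ontology-out onto.json
cytotext validate --bioc corpus.xml --ontology onto.json
cytotext sample --pool corpus.xml --n 50 --seed 7 --out selected.xml
cytotext split --bioc corpus.xml --seed 7 --out split.json
cytotext iaa --a first.xml --b second.xml --mode all --by-passage-type
cytotext ner-eval --gold gold.xml --pred pred.xml --span exact --labels typed
cytotext link --mentions corpus.xml --ontology onto.json --k 10 --out preds.tsv
cytotext el-eval --gold corpus.xml --pred preds.tsv --mode all_ids
cytotext coverage --ids ids.txt --ontology onto.json
cytotext motif-types
```

Corpora are BioC XML; ontologies load from an OBO-graph JSON subset or a
3-column TSV edge list (child, parent, label).

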