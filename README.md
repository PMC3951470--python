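# ppimkl

Multiple-kernel learning toolkit for protein–protein interaction (PPI)
extraction from entity-tagged, pre-parsed sentences. Three kernels are
implemented and combined linearly for an SVM with precomputed Gram matrices:

- **Feature kernel** (`ppimkl.feature_kernel`) — lexical word groups
  (words in the protein names, between them, in a ±5-token window), a single
  interaction-keyword feature, a binned between-distance and a count of other
  proteins between the pair; cosine similarity over one-hot encodings.
- **Dynamic extended tree kernel** (`ppimkl.tree_kernel`) — Collins–Duffy
  convolution kernel on pruned constituency trees. Pruning keeps the
  shortest-path-enclosed tree (SPT) when it is large enough, and otherwise
  widens it to the minimum complete tree (MCT) or to the subtree rooted at the
  parent of the SPT root.
- **Semantic kernel** (`ppimkl.semantic_sim`) — protein-pair similarity over a
  concept taxonomy (hybrid of edge-counting and information-content measures)
  plus context similarity via maximum-weight bipartite matching
  (Kuhn–Munkres) of word similarities.

Supporting modules: `corpus_io` (JSONL instance format, Penn-Treebank tree
I/O, taxonomy TSVs, protein masking), `ensemble_model` (kernel ensembling,
PSD repair, SVM training, 10-fold cross-validated P/R/F + ROC/AUC),
`synthetic_data` (seeded corpora and toy taxonomies with controllable
signal) and `cli` (command-line interface).

## CLI

```sh
# generate a synthetic corpus + concept/word taxonomies
ppimkl simulate --n 400 --positive-rate 0.3 --keyword-signal 0.8 \
    --taxonomy-signal 0.8 --seed 42 --out corpus.jsonl --tax-prefix tax

# extract feature vectors
ppimkl features --corpus corpus.jsonl --window 5 --out features.jsonl

# compute a Gram matrix (TSV) for one kernel or a weighted ensemble
ppimkl gram --corpus corpus.jsonl --kernels det --lambda 0.4 --threshold 7 \
    --out K_det.tsv
ppimkl gram --corpus corpus.jsonl --kernels fea,det,sim --tax-prefix tax \
    --weights 1,1,1 --out K.tsv

# 10-fold cross-validated SVM evaluation
ppimkl eval --corpus corpus.jsonl --kernels fea,det,sim --tax-prefix tax \
    --folds 10 --split document --seed 42 --C 1.0 --report out/
```

Every command accepts `--config run.toml` (flags override file values) and
writes a manifest JSON recording all effective parameters next to its
outputs; identical configurations produce byte-identical artifacts.

## Data formats

- **Corpus**: JSONL, one instance per line with
  `{id, doc_id, tokens, entities[{start,end,role,concept_id}], parse, label}`.
  Spans are 0-based half-open; `parse` is a Penn-Treebank bracketed string
  whose leaves equal the tokens; roles are `P1`, `P2`, `OTHER` with P1
  preceding P2.
- **Taxonomy**: TSV edge list (`child<TAB>parent`) plus TSV frequency table
  (`concept<TAB>count`); must be a single-rooted DAG.
- **Gram matrices**: TSV with an id header and labeled rows.

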