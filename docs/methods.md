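# Methods

## Problem and model

The package scores pairs of clinical-style sentences for semantic
similarity on the 0–5 rubric used in clinical sentence-similarity
benchmarks (0 = unrelated, 5 = equivalent). The model fuses two views of a
pair:

1. **Text view.** The pair is encoded jointly as one token sequence
   `sentence1 [SEP] sentence2`. The built-in encoder is a small
   transformer-style network: token embeddings plus learned position
   embeddings, `n` single-head self-attention blocks with relu residual
   connections, mean-pooled over non-pad positions. Production-scale
   pretrained checkpoints are supported through an adapter contract (any
   callable `(text1, text2) -> vector`); the package deliberately bundles
   no checkpoints.
2. **Graph view.** Each sentence is tagged with terminology concepts
   (dictionary longest-match tagger, or parsed external tagger output),
   and its concept graph is induced from the terminology graph as the
   union of one shortest path per unordered pair of tagged concepts. A
   graph convolutional encoder with the symmetric-normalized propagation
   rule with self-loops, `H' = act(D̃^{-1/2}(A+I)D̃^{-1/2} H W)`, is
   applied (shared weights for both sentences' graphs) and mean-pooled
   into one vector per graph. Node features come either from a pretrained
   concept-embedding table or from a seeded random draw.

The text vector and the two graph vectors are concatenated and passed to a
feed-forward scoring head: one relu hidden layer, then a linear map to a
single real score. The hidden layer is load-bearing: similarity between
the two graph vectors is a symmetric interaction, and a purely linear map
on a concatenation cannot express any function of the *relation* between
`g1` and `g2`, while one hidden layer realizes distance-like features such
as `|u·(g1 − g2)|`. Predictions are clamped to [0, 5] only at reporting
and ensembling time; training regresses the raw score.

## Terminology graph and subgraph induction

Concept and relation files are pipe-delimited in the standard layout
(concept identifier, source vocabulary and name string at their usual
column positions; the column map is configurable for miniature dialects).
The graph is undirected, unweighted and untyped: relation labels are
retained on the parsed rows but never affect topology. Shortest paths are
unweighted; among equal-length paths the lexicographically smallest CUI
sequence is chosen, which makes induction deterministic and gives it a
clean independent oracle (the minimum over all enumerated shortest
paths). Seeds absent from the terminology graph are dropped with a
warning; seed pairs in different components contribute nothing, so such
seeds remain as isolated nodes. Duplicate concepts within a sentence
collapse to one seed.

## Augmentation

Two rules, applied before encoding:

- **Concept append.** Each sentence is extended with the space-joined
  preferred names (then semantic types) of its tagged concepts, in mention
  order, duplicates dropped keeping the first occurrence, separated from
  the original text by a single space. The append order
  (names before types) and the deduplication are this package's canonical
  choices; the rule itself exists because preferred names expand
  abbreviations (e.g. "pacu" → "postoperative anesthesia care unit
  (PACU)").
- **Reverse-pair doubling.** The dataset is doubled with swapped copies of
  every pair (scores and categories preserved), signalling that the task
  is symmetric in sentence order. Copies are appended after the originals
  so dataset order is deterministic.

## Training, distillation, ensembling

Training minimizes mean squared error with Adam under two learning-rate
groups — text encoder vs graph encoder + head. `TrainConfig` defaults
(1e-4 text, 1e-3 graph, 4 epochs) are the published fine-tuning values for
pretrained text encoders. The benchmark recipe
(`pipeline.BENCHMARK_TRAIN_CONFIG`) instead uses 1e-3 for both groups and
14 epochs with batch size 16: the built-in encoder trains from scratch,
and a fine-tuning rate of 1e-4 over 4 epochs leaves it essentially
untrained. Shuffling, initialization and all random feature draws are
seeded; two runs with the same configuration produce identical parameter
trajectories and identical output files.

Knowledge distillation uses the teacher-bounded regression loss

    L = (s − y)² + ν·B,   B = (s − t)²  if (s − y)² + m > (t − y)²,
                          B = 0         otherwise,

with student s, teacher t, gold y, margin m and weight ν. The switching
condition is evaluated on current values and carries no gradient. Defaults
m = 0, ν = 0.5 are package choices (the constants are not fixed by the
loss's definition). With ν = 0 the trajectory is identical to plain MSE
training under equal seeds.

Ensembles average member scores in the raw output space and clamp the mean
to [0, 5]; members may be fusion models or any scorer exposing the same
predict contract. Multisource variety is realized as seed/configuration
variety, since checkpoint variety is not reproducible without external
weights.

## Evaluation

Pearson product-moment correlation (scipy), overall and per category
(status / education / meds / miscellaneous, given as labels, never
inferred). Undefined correlations — fewer than two points or a constant
vector — are reported as missing rather than zero. Splits are seeded
shuffles followed by prefix partitions.

## Synthetic benchmark

The generator emulates the statistical structure of a clinical
sentence-similarity corpus with its terminology, without emulating
clinical language:

- **Ontology**: uniform random spanning tree (Prüfer decoding) over
  `n_concepts = 200` concepts plus `0.3·n` extra random edges; connected
  by construction; serialized in the pipe-delimited terminology dialect.
- **Lexicon**: 2 distinct single-token surface forms per concept sharing
  one CUI — a text-only model sees unrelated tokens where the graph sees
  one node.
- **Embeddings**: spectral layout (eigenvectors of the symmetric
  normalized Laplacian for the smallest nonzero eigenvalues, sign-fixed,
  16 dimensions), so graph-proximal concepts receive nearby vectors.
- **Pairs**: 2000 pairs; per pair a relatedness level r ~ U(0,1) controls
  the number of shared concepts and whether partner concepts are drawn
  from a 2-hop neighborhood (r > 0.5) or uniformly. Latent similarity is
  `0.3·J + 0.7·G` with J the multiset Jaccard overlap of surface tokens
  and G the mean cross-pair proximity kernel `1/(1+d)`; the gold score is
  `clamp(5·latent + N(0, 0.3), 0, 5)`. Categories cycle round-robin and
  exist only to exercise the per-category evaluator.

The kernel `1/(1+d)` was chosen because it is bounded, monotone in
distance and hand-computable in tests. Because `w_graph = 0.7` and
synonyms split surface forms, the correlation between gold scores and
pure lexical overlap is strictly below the correlation between gold
scores and the latent similarity — the planted signal is accessible only
through graph proximity.

What passing on this benchmark does **not** show: robustness to clinical
language (abbreviation ambiguity, negation, protected-health-information
patterns), annotator disagreement structure, or transfer of the absolute
correlation levels to real corpora. The benchmark tests the machinery and
the qualitative ordering of model variants, not clinical performance.

## Benchmark protocol and problem sizes

Each benchmark seed generates a fresh corpus, split 65/15/20 into
train/validation/test (seeded shuffle). Five full models (pretrained node
features) are trained with varied seeds; their mean held-out Pearson is
reported as the full model's performance and their score average as the
ensemble. One random-initialization variant and one text-only ablation
(graph vectors zeroed) are trained with the same recipe. Reverse-pair
doubling is applied to the training split; concept-name appending is off
in the benchmark so the text ablation is not handed concept identity
through the text channel. The built-in encoder runs with embedding width
64, one attention block and maximum joint length 32 (synthetic sentences
are short); the graph encoder uses two 32-wide layers over the 16-d
spectral features; the head hidden width is 32. These sizes are the
package's desk-scale defaults.

## Numerical choices and degenerate inputs

- All float math is float64; the autodiff engine is a minimal tape with
  the operations the models need, gradient-checked against central finite
  differences.
- The empty concept graph encodes to the zero vector; all-pad token rows
  encode to the zero vector; masked attention uses additive −1e9 logits.
- Out-of-table concepts in pretrained initialization receive seeded
  random rows (per-position sub-seeds), leaving in-table rows bit-stable
  across seeds.
- Equal-length shortest paths tie-break lexicographically; node orderings
  in induced graphs are sorted, so adjacency matrices are reproducible.

## Known limitations

- The built-in text encoder, trained from scratch on a few thousand
  pairs, captures only part of the lexical-overlap signal; its role is to
  exercise the contract and the fusion, not to rival pretrained
  encoders. Absolute benchmark correlations are accordingly modest
  (~0.25 full model vs ~0.9 noise ceiling); the assertions target the
  ordering between variants, mirroring the qualitative result that
  knowledge-initialized graph fusion > randomly initialized graph fusion
  > text only.
- The dictionary tagger does no disambiguation or negation handling.
- Token vocabulary is built over the whole corpus (transductive); unseen
  tokens at inference map to the unknown id.
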