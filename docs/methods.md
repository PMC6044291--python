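# Methods

## Problem and model

`chemrel` detects and classifies chemical–protein interactions in
PubMed-style abstracts annotated in the CHEMPROT format: each document
carries chemical and gene/protein mention spans, and relations between one
chemical and one gene mention fall into five evaluated CPR groups —
upregulator/activator (CPR:3), downregulator/inhibitor (CPR:4), agonist
(CPR:5), antagonist (CPR:6) and substrate/product (CPR:9). The task is cast
as 6-way classification of candidate mention pairs (the sixth class being
"no relation"), scored as micro-averaged precision/recall/F over unique
(document, group, chemical, gene) tuples.

Every chemical × gene pair whose mentions lie within a 60-token window is a
candidate. Its input is the token window from 5 tokens before the earlier
mention to 5 after the later one, with the candidate chemical's tokens
replaced by `$CHEMICAL`, the gene's by `$PROTEIN`, and tokens in both by
`$BOTH`, so the classifier cannot latch onto particular entity names. Two
aligned binary feature sequences accompany the tokens: a 10-bit sequence
marking, per token, the five span-overlap relations (inside / at start / at
end / overlapping start / overlapping end) against *any* chemical and any
gene mention in the document, and a 2-bit sequence marking membership in
the candidate pair itself.

The classifier is a recurrent network: a 300-dimensional embedding `e1`, a
forward LSTM `l1` and a backward LSTM `l2` (300 units each, per-position
outputs) over the masked tokens; width-3 relu convolutions over the two
feature sequences (48 and 6 filters); the per-position concatenation of all
four (300+300+48+6 = 654 wide) feeds a bidirectional LSTM of 128 units per
direction, a per-feature max over positions, and a 6-way softmax trained
with mean squared error against the one-hot label. All LSTMs use dropout
and recurrent dropout of 0.5 during training; the optimiser is RMSProp.

## Transfer learning by negative-sample discrimination

Before and between the first relation-training epochs, the shared layers
(`e1`, `l1`, `l2`) are trained on unlabelled text. Each line is tokenized
and each token replaced, with probability 0.5, by a token drawn
(occurrence-weighted) from the 12 000 lines of the current sub-epoch. The
pre-training network sees the original sequence plus the substituted
sequence shifted one position right and one left; for each position and
each direction a 300-unit relu layer and a 1-unit sigmoid head decide
whether the shifted token is original (1) or a negative sample (0), against
the left- and right-hand LSTM context respectively. The loss is binary
cross-entropy, masked at shift- and batch-padding positions and averaged
over the two heads. Because the parameter tensors are shared by identity,
every phase-1 update is immediately visible to the recognition network;
nothing is frozen afterwards.

The schedule runs `n_epochs` epochs; each of the first five runs phase 1
(25 sub-epochs of 12 000 lines at full scale, configurable 0–25) followed
by one pass over the training candidates, later epochs phase 2 only. After
every epoch the development split is scored with plain argmax decisions and
the epoch with the best dev F is selected (ties to the earliest).

## Decision rules

Besides the argmax over all six outputs, a post-hoc rebalancing rule takes
the best positive class x (argmax over the five relation scores, value o_x)
and the NONE score o_0 and accepts x iff a statistic exceeds a threshold:
a = o_x, b = o_x − o_0, or c = o_x / o_0 (+∞ when o_0 = 0; comparison is
strict). Formula and threshold are fitted jointly by maximising dev micro-F.
Since F changes only at observed statistic values, the search grid of
midpoints between consecutive distinct dev values, plus one point below the
minimum and one above the maximum, is exact, and it always contains a rule
equivalent to the argmax decision (b at 0), so fitting can never fall below
the argmax baseline on the data it was fitted to.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `emb_dim` | 300 | embedding width; scaled runs use 24 |
| `shared_lstm_units` | 300 | l1/l2 width; scaled 24 |
| `l3_units_per_direction` | 128 | second-stage BiLSTM; scaled 16 |
| `i4_conv_filters`, `i5_conv_filters` | 48, 6 | feature convolutions, width 3 |
| `dropout`, `recurrent_dropout` | 0.5 | on all LSTMs, training only |
| `learning_rate` | 0.001 | RMSProp (ρ = 0.9, ε = 1e-8) |
| `max_distance` | 60 | candidate window, inclusive token-index bound |
| `context` | 5 | tokens kept either side of the pair |
| `min_count` | 2 | tokens seen once are out-of-vocabulary |
| `batch_size` | 32 | both phases, length-grouped |

Vocabulary indices 0–4 are reserved (padding, unknown, the three masks);
reserved rows and tokens absent from the supplied word-vector table start
at zero and are trainable. The vocabulary is built from the task training
corpus only and shared with the pre-training text, which is what lets the
shared embedding transfer.

## Numerical and design choices

* The networks run on a small reverse-mode autodiff engine over numpy
  (`chemrel.nn`): eagerly built graphs, float64, exact Jacobian for the
  softmax, fused sigmoid/binary-cross-entropy for stability. Gradients are
  verified against central differences in the test suite.
* The backward LSTM processes the reversed sequence and its outputs are
  re-reversed, so position t of `l2` summarises context at and right of t;
  this pairs it correctly with the left-shifted input in the pre-training
  network.
* The concatenation feeding the second BiLSTM is the sum of its parts,
  654 wide at defaults (300+300+48+6).
* LSTM kernels are glorot-uniform, recurrent kernels orthogonal, forget
  bias 1; dropout masks are sampled once per sequence and reused across
  timesteps (the usual recurrent-dropout treatment).
* Convolutions use same-length zero padding so their outputs align
  position-for-position with the LSTM outputs.
* Phase-1 losses at padded positions are masked out; including them would
  let the network learn the padding symbol trivially. The two directional
  losses are averaged.
* A replacement is counted as a replacement even when the sampled token
  equals the original: the target records the substitution event.
* Pre-training lines are read sequentially with a cursor that cycles at end
  of file and restarts with each training run, so runs with equal seeds are
  bit-reproducible; all other randomness flows from one seeded generator.
* Candidate pairs with several gold groups (rare annotation overlaps)
  resolve to the lowest-numbered group, deterministically, with a warning.
* Multiple mention pairs predicting the same relation tuple count once in
  evaluation (tuple-level deduplication); the confusion matrix is computed
  per candidate, not deduplicated.
* Percentages are reported to two decimals, half-up.
* Tokenization: whitespace split, then iterative stripping of leading and
  trailing sentence punctuation and unbalanced brackets as separate tokens.
  Internal hyphens, digits and balanced brackets stay inside the token, so
  "COX-2" and "(S)-ibuprofen" survive intact. The tokenizer is pluggable;
  fidelity to any particular chemistry tokenizer's treatment of Greek
  letters, unicode dashes or nested brackets is not claimed.

## The synthetic corpus

Full-scale training data (the CHEMPROT corpus, a 24-million-line unlabelled
PubMed file, multi-gigabyte word vectors) cannot ship with a desk-scale
package, so `chemrel.synthetic` generates all three inputs:

* **Abstracts** are concatenations of template sentences: a relation
  sentence `<chemical> [adverb] <trigger> <protein> [suffix]`, a
  co-occurrence sentence (`<chemical> and <protein> were measured`), and
  entity-free distractors. Character offsets are exact; gold relations list
  one record per relation sentence. Trigger lexicons are pairwise disjoint
  and determine the CPR group, so label identifiability is perfect: an
  oracle reading only the trigger scores F = 100. That known ceiling
  separates pipeline defects from modelling noise in end-to-end tests.
* **Defaults are calibrated to the real corpus's candidate statistics**
  (roughly 50 candidate pairs per abstract with 8–10 % carrying a
  relation, as in the CHEMPROT development split): 7–10 sentences per
  abstract, distractor rate 0.15, non-relation fraction 0.3, 40 chemicals
  and 40 proteins in the lexicons. At 300 abstracts this yields ≈16 000
  training candidates, ≈9.5 % positive.
* **Pre-training text** comes from a first-order Markov grammar over the
  same ≈200-token inventory, each token allowing three successors with
  probabilities (0.7, 0.2, 0.1). Transitions are strongly non-uniform, so
  substituted tokens are statistically detectable and the discrimination
  task is learnable; the inventory overlap makes phase-1 transfer
  meaningful.
* **Toy word-vector files** contain seeded uniform [−1, 1] vectors. They
  carry no distributional signal, so the canonical end-to-end experiment
  uses random embedding initialisation; vector-file loading and embedding
  assembly are exercised by their own tests.

What the synthetic corpus does *not* emulate: negation, coordination,
anaphora, cross-sentence relations, entity-boundary ambiguity, class
imbalance between the five groups, and annotation noise. Passing the
synthetic recovery test therefore demonstrates that the pipeline and the
learning machinery are correct, not that real-corpus F scores are
reproduced; real performance depends on phenomena the generator excludes.

## Scaled study conditions

The canonical desk-scale experiment (`chemrel.pipeline`) trains the scaled
architecture (embedding 24, shared LSTM 24, second-stage 16 per direction)
for 10 epochs on 300 synthetic abstracts with three 500-line sub-epochs of
phase 1 in each of the first five epochs, and evaluates on a held-out
60-abstract split (fixed generation seeds; the run seed drives training
randomness). Typical results: dev micro-F around the low 90s at the
selected epoch, against the ceiling of 100, with a seed-to-seed spread of
roughly 80–98 — the network is still on the steep part of its learning
curve at epoch 10, and dropout at width 24 is a strong noise source.
Held-out discrimination accuracy of the pre-training task is ≈ 0.7
(chance 0.5) after the scaled phase 1.

## Known limitations

* Sequence-level max pooling runs over padded positions as well; batches
  are length-grouped precisely to keep padding minimal, but a pathological
  batch mix could let padding states leak into the pooled features.
* The threshold grid is exact for the development set it is fitted on;
  nothing guards against overfitting the rule to a tiny dev set.
* The numpy engine is single-threaded and eager; it is sized for the
  desk-scale experiments, not for full-corpus training.
* Candidates are emitted per mention pair without deduplication; documents
  repeating the same entity pair contribute several instances (their
  predictions merge at evaluation time).
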