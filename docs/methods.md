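# Methods

## Model

`epipair` learns one embedding model per regulatory role. Each DNA sequence
is rendered as an ordered sentence of k-mer words (stride *s*, trailing
bases that do not complete a window are dropped, so a sequence of length
*L* yields `floor((L − k)/s) + 1` words). Every word and every document
(sequence) owns a vector in R^d; a sliding m-word context predicts the next
word from the concatenation `h = (w_1, …, w_m, x_doc) ∈ R^{(m+1)d}`. The
document vector is shared by all contexts of its own sentence, word vectors
are shared corpus-wide, and only full-length contexts contribute (sentences
with T ≤ m are skipped with a warning, matching the objective's summation
range). After SGD training, the document vectors are the sequence features.

Two output layers implement the same probability contract (a proper
distribution over the vocabulary for the next word):

* **exact softmax** `y = b + Uh`, practical only for small vocabularies and
  used as a reference backend in tests;
* **hierarchical softmax** (default) over a binary Huffman tree built from
  corpus word frequencies; a leaf's probability is the product of branch
  sigmoids σ(±v_n·h) along its root path, so probability mass is conserved
  by construction and frequent words have short evaluation paths.

Ambiguous windows (any non-ACGT base) map to a reserved UNK index: they are
kept as context — so the token-count formula and window phase never change
— but are never prediction targets and own no Huffman code. Huffman merges
are tie-broken by the lexicographically smallest token inside each subtree,
making the tree, and therefore the whole model, reproducible.

The supervised stage concatenates the two document vectors of a pair
(200 dimensions at the default d = 100), optionally appends an external
per-pair feature table, and fits a gradient-boosted ensemble of depth-D
regression trees with logistic loss (`scikit-learn`'s
`GradientBoostingClassifier`). Evaluation is stratified 10-fold
cross-validation; F1 uses the 2rp/(r + p) form with decisions at score
≥ 0.5 and is defined as 0 when precision + recall is 0.

The attention weight of word *t* in sequence *i* is
`α_it = exp(x_i·w_t) / Σ_j exp(x_i·w_j)` with the sum over that sentence's
own tokens. Duplicate words within a sentence receive identical weights and
are deduplicated only at export.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| k | 6 | word length, vocabulary ≤ 4^k |
| s | 1 bp | window stride |
| m | 20 | context words per prediction |
| d | 100 | embedding dimension |
| epochs | 20 | full passes over the corpus |
| lr0 → lr1 | 0.025 → 1e-4 | linear learning-rate decay across all updates |
| GBRT α, n, D | 1e-3, 4000, 25 | learning rate, trees, depth |
| folds | 10 | stratified cross-validation |

Epoch count and learning rates have no canonical values for this model
class; the decay schedule and the defaults above are this package's
choices, exposed in `TrainConfig` and logged by every CLI command. Word
vectors and document vectors initialise uniformly in ±0.5/d from the seeded
generator; output-layer parameters start at zero (so an untrained model is
exactly uniform over the vocabulary). Training visits contexts
left-to-right within each sentence and reshuffles sentence order every
epoch from the same generator; single-worker runs are bit-reproducible
given a seed.

Two embedding modes are provided because the unsupervised stage is
naturally transductive (it may embed every sequence, including future test
items, without seeing labels): `embed` returns the trained document vector,
and `infer_vector` optimises a fresh document vector with word and
output-layer parameters frozen, for held-out sequences. Cross-validation
re-uses the single transductive run by default and offers a strict mode
that re-infers test-fold vectors.

## Synthetic study conditions

The generator emulates the structure of EPI benchmark sets: variable-length
sequences, cell-type-like regulatory programs realised as planted PWM
motifs, and distance-controlled pair sampling.

* 400 enhancers (250–600 bp) and 400 promoters (600–1000 bp), i.i.d.
  uniform background composition;
* each sequence carries one of two programs (A or B, equiprobable),
  realised by a role- and program-specific 10-bp consensus PWM
  (per-position consensus probability 0.9) planted at non-overlapping
  uniform positions — 18 copies per enhancer, 24 per promoter (promoters
  are longer, so copy numbers keep motif density comparable);
* sequences receive coordinates on a 50-Mb virtual chromosome; candidate
  pairs closer than 10 kb or farther than 2 Mb are discarded;
* an A-enhancer × A-promoter candidate interacts with probability 0.9, all
  other combinations with probability 0.05, giving labels irreducible
  noise; 200 positives are drawn, and 200 non-interacting candidates are
  subsampled as negatives matched to the positive distance distribution
  across 5 quantile bins (one negative per positive).

The copy numbers and PWM sharpness were calibrated, once, against a simple
6-mer-count logistic baseline (implemented only in the test suite) so the
dataset is neither trivial nor impossible: the baseline reaches 10-fold F1
≈ 0.80 (band 0.70–0.85), against an oracle ceiling of ≈ 0.90 for a
classifier given the true program tags. The generator captures planted,
position-independent motif signal only; it has no chromatin state, no GC
heterogeneity, no repeat structure, no shared promoters between genes, and
its interaction rule is a single compatibility bit — so passing recovery
tests demonstrates that the pipeline extracts planted sequence programs at
realistic noise levels, not that it would reach any particular accuracy on
real Hi-C-derived data.

## Study scales

The full-corpus defaults (k = 6, m = 20, d = 100, 4000 trees) are sized for
corpora of tens of thousands of sequences. The bundled study runs on a
~200 kb/role corpus and uses models sized to it, fixed once in
`epipair.pipeline`:

* classification runs: k = 3, m = 1, d = 12, lr0 = 0.05, 25 epochs for
  enhancers and 12 for promoters (promoter sentences are about twice as
  long, so they see about the same number of SGD updates), GBRT with
  α = 0.1, n = 300, D = 3. A 64-word vocabulary is densely observed at
  this corpus size, which keeps word and path parameters well estimated;
  with these scales the pipeline reaches mean 10-fold F1 ≈ 0.82–0.85
  while shuffled labels stay at ≈ 0.5.
* attention runs: identical but k = 6, because per-word interpretability
  requires motif-scale words; with k = 3 the planted programs are still
  classifiable from the document vectors, but single words are too common
  to be individually informative.

## Numerical choices and degenerate inputs

Sigmoid arguments are clipped at ±30; attention and exact-softmax
computations subtract the maximum logit before exponentiation. Sequences
shorter than k tokenize to empty sentences with a warning rather than an
error; empty corpora, single-word vocabularies (no Huffman tree), corpora
in which no sentence exceeds the context length, single-class label
vectors, and fold counts exceeding the minority class all raise immediately
with actionable messages. Model files are a versioned container (JSON
header plus raw array blocks) written deterministically, so fixed-seed
reruns are byte-identical.

## Known limitations

* Training is single-threaded; there is no negative-sampling objective and
  no PV-DBOW variant.
* The hierarchical softmax and the exact softmax share the probability
  contract but not parameters, so likelihoods are comparable only within a
  backend.
* Inference for unseen documents is implemented for the hierarchical
  backend only.
* On the synthetic corpora the count-based logistic baseline is a strong
  competitor (planted-motif signal is exactly count signal); the embedding
  pipeline's advantage there is compactness and interpretability of its
  features, not raw accuracy.
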