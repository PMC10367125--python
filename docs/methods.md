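# Methods

## Problem and model

`methyllm` predicts whether the base at the center of a 41-nt DNA window is
methylated, for three methylation types: N6-methyladenine (6mA, center base
A), N4-methylcytosine (4mC, center base C) and 5-hydroxymethylcytosine
(5hmC, center base C). The prediction is phrased as a text-classification
problem: each window is rendered as a sentence of its 36 overlapping 6-mer
"words" (a sliding window of length 6 over 41 nt gives 41 − 6 + 1 = 36
words) followed by a templated English description of the organism's
8-rank taxonomic lineage ("For this organism, its species is …, its genus
is …, …, its domain is …"). Including the lineage as an explicit text
feature lets a single classifier per methylation type serve many organisms
and lets attention analysis relate sequence positions to taxonomic ranks.

Five transformer-encoder language models (configuration presets named
after the families they follow: BERT, DistilBERT, ALBERT, XLNet, ELECTRA)
are each adapted with the pretrain-and-fine-tune paradigm and combined by
averaging their predicted probabilities — an unweighted arithmetic mean,
with no stacking, weighting or calibration.

## Transformer engine

Because the package must run anywhere a plain scientific-Python stack is
available, the encoder is implemented directly in NumPy with exact manual
backpropagation rather than on top of a deep-learning framework. Each
encoder block computes multi-head scaled dot-product self-attention

    MultiHead(Q, K, V) = Concat(head_1, …, head_h) W^O
    head_i = Attention(Q W_i^Q, K W_i^K, V W_i^V)
    Attention(Q, K, V) = softmax(Q K^T / √d_k) V

with the row-softmax over keys included (without it, attention rows would
not be the normalised weight distributions that the interpretability
analysis sums), padding keys masked out with a large negative additive
bias, followed by a GELU feed-forward sublayer. Blocks use pre-LayerNorm
residual wiring with a final LayerNorm, which trains stably at tiny scale
without a learning-rate decay schedule; there is no dropout, so evaluation
is deterministic and training is bit-reproducible for a fixed seed on a
single thread. Parameters are trained with Adam under linear warmup to a
constant learning rate. Everything runs in float64.

Two architecture presets exist: `paper` (12 layers, 768 hidden units, 12
heads — the published configuration, included for completeness but not
trained here) and `tiny` (2 layers, 64 hidden units, 4 heads, feed-forward
128), the desk-scale configuration used in all tests. Head dimensions are
d_k = d_v = hidden/heads, and the input embedding size must equal the
tokenizer vocabulary size (checked before training).

## Tokenizers

One tokenizer is trained per family on the pretraining corpus. Vocabulary
induction is frequency based: the five special tokens ([PAD], [UNK],
[CLS], [SEP], [MASK]), single-character fallback pieces, then whole
whitespace-level words in descending corpus frequency (ties broken
lexicographically, so training is deterministic) up to the target
vocabulary size (default 25,000). Out-of-vocabulary words are segmented by
greedy longest match; the WordPiece-style families (BERT, DistilBERT,
ELECTRA) mark continuation pieces with `##`, the SentencePiece-style
families (ALBERT, XLNet) mark word-initial pieces with `▁`. On a corpus of
6-mer DNA sentences the behaviour at realistic vocabulary sizes is the
property that matters: every corpus 6-mer and lineage word is a single,
word-aligned token. All text is lowercased (uncased configuration).

Encoded samples are `[CLS] content [SEP]` padded with `[PAD]` to exactly
100 positions. If tokenized content overflows, pieces are dropped from the
tail of the taxonomy clause first; the 36 DNA tokens are truncated only as
a last resort (the DNA is the primary signal and always fits when
in-vocabulary). Word/token alignment, the DNA token span and each rank
name's token span are recorded at encoding time for interpretability.

## Pretraining

The corpus contains every processed training sentence plus one lineage
sentence for each extra lineage whose 8-rank tuple does not already occur
in the training data (deduplication is by exact tuple; sentences
themselves are kept in input order and not deduplicated). Objectives by
family:

* **Masked language modelling** (BERT, DistilBERT, ALBERT): 15% of
  non-special tokens are independently selected as candidates; of these
  80% become [MASK], 10% a random non-special vocabulary token, 10% stay
  unchanged, and the original tokens are predicted. Selection is
  per-token Bernoulli (expected 15%), matching the reference
  implementations this recipe follows. Next-sentence prediction is not
  used.
* **Replaced-token detection** (ELECTRA): ~15% of content tokens are
  replaced by draws from the corpus unigram token distribution and a
  per-token discriminator head predicts which tokens were replaced.
  Corruption is sampled rather than produced by a learned generator; at
  tiny scale a generator adds cost without changing what the objective
  exercises.
* **Permutation partial prediction** (XLNet): the targets are the final
  ~15% of a random factorisation order of each sample's content tokens,
  hidden and predicted from the remaining context. The two-stream
  attention mechanism is omitted — with a bidirectional encoder and
  masked targets the objective is well-posed without it.

Published defaults: 8 epochs, batch 64, learning rate 5e-4, 100 warmup
steps. A held-out corpus slice (10%) is used only to record the objective
loss before training and after each epoch.

## Fine-tuning cascade

Each methylation type's classifier is a 2-way softmax head on the final
[CLS] hidden state. Types are fine-tuned in a cascade ordered by
decreasing training-set size — 6mA from the pretrained model, 4mC from the
6mA model, 5hmC from the 4mC model — so the smaller subsets start from an
already task-adapted model. Provenance (checkpoint SHA-256 of the parent)
is recorded at each stage; the cascade API enforces the order, while
single-stage fine-tuning remains available explicitly.

Internally each subset is split 8:2 into train/validation; the split is
stratified by label (balanced datasets stay balanced in both parts, at
most ±1 sample per class from the exact share). Published defaults: at
most 32 epochs, batch 64, learning rate 1e-5, 100 warmup steps. Early
stopping monitors the validation loss (the least-assumption choice among
unstated alternatives) with a patience of 3 evaluations, and the
best-validation checkpoint is returned.

## Ensemble and evaluation

The ensemble probability is the exact arithmetic mean of the member
probabilities; classification uses p ≥ 0.5 as positive (a symmetric
default for balanced data; the threshold is configurable). Metrics (AUC,
accuracy, F1, recall, AUPR, ROC points) are computed with scikit-learn;
AUC follows the Mann–Whitney convention (ties count ½) and is
cross-checked in the tests against an O(n²) pair-counting oracle, AUPR
against a direct step-sum enumeration. One-class inputs mark AUC/AUPR as
NaN while threshold metrics are still computed. A missing ensemble member
triggers a warning, not an error.

## Interpretability

The classifier consumes the [CLS] representation, so token importance is
read from the final encoder layer's attention anchored at [CLS], summed
over heads. Two directions are supported: `cls-query` (default) uses the
row in which [CLS] is the Query — the distribution the classifier head
actually consumes, under the convention that a_ij is the weight Query
token t_i receives from Key token t_j — and `cls-key` sums each token's
attention toward [CLS] as Key. Scores are aggregated to words (sum over a
word's pieces); because the WordPiece-style tokenizers give word-aligned
tokens, the word scores of the three WordPiece-family submodels
(BERT, DistilBERT, ELECTRA) fine-tuned for the sample's methylation type
are averaged. Only the final encoder layer is used; summing across all
layers is a plausible alternative the package does not implement.

Position importance merges the 36 DNA-word scores into a length-41
profile: position p is covered by between 1 and 6 words (min(p, 41−p+1, 6)
of them) and takes the mean of its covering words' scores (sum available
via a flag). Motif discovery ranks distinct 6-mers by their mean word
score over a set of positive samples and reports the top n (default 10)
with occurrence counts. DNA→taxonomy attention sums, per DNA word and
per rank, the final-layer head-summed attention from the word's tokens to
the rank name's tokens, yielding a 36 × 8 matrix.

## Genome scanning

For a contig, every position 21 ≤ p ≤ L−20 holding the target base yields
a candidate window (windows containing non-ACGT characters are skipped and
counted). Step 1 keeps windows whose ensemble probability reaches the
threshold; step 2 retains a kept window only if its 41-position importance
profile (averaged over the word-wise submodels) attains its maximum at the
center. Ties retain by default — a plateau including the center should not
reject a site — with a strict unique-maximum mode available. Only the
given strand is scanned unless `both_strands` is set, in which case the
reverse complement is scanned too and the strand reported. Output is TSV
(1-based centers) and BED (0-based half-open single-base intervals).

## Synthetic data

The generator emulates the structure of the public 41-nt benchmarks
without reproducing any real biology: balanced classes, uniform base
composition, positives carrying a planted 6-mer consensus at an offset
overlapping the center with the center base forced to the target, and an
8-rank lineage assigned round-robin from a small built-in set. Default
consensi (6mA: AGACAT; 4mC/5hmC: TCCGCA) contain the target base at three
different offsets, so the motif position varies across positives while the
forced center base never corrupts the consensus. Negatives also carry the
target center base — the class signal is the motif, not the base — and are
rejection-sampled to exclude the exact consensus; degenerate matches are
deliberately allowed. Synthetic chromosomes plant motif-bearing windows at
recorded centers with pairwise spacing ≥ 41.

What passing tests on this data show: that every mechanism — encoding,
tokenization, the training objectives, the cascade, averaging, the
attention analyses, the scanning filter — behaves as specified and that
the whole pipeline can learn a strong planted signal. What they do not
show: performance on real methylomes, where motifs are degenerate,
composition is biased, classes are imbalanced across taxa, and lineage
effects are genuine rather than round-robin decoration.

## Problem sizes and numerical choices

All trained tests use the `tiny` preset with desk-scale study conditions:
400-sample training sets (200 per class) per type for 6mA and 240 for
4mC/5hmC, vocabulary 6,000, pretraining 1–2 epochs and fine-tuning up to
8 epochs at batch 16 with learning rates 5e-4 / 2e-4 and 20 warmup steps
— small enough that the full suite runs on one CPU, large enough that
held-out AUC on the planted-motif task is essentially 1. Stochastic
properties (motif recovery in the top-10 table, center-biased importance)
are evaluated over 10 fixed-seed replicates with an 80% pass requirement;
training at this scale occasionally converges to solutions whose [CLS]
attention does not isolate the motif word, which is genuine optimisation
variance rather than a defect of the scoring.

Numerical details: float64 throughout; attention row sums hold to 1e-5 by
construction (softmax); probabilities are exact softmax outputs; the
center-max filter compares with a 1e-12 tolerance; all randomness flows
through explicitly seeded `numpy.random.Generator` instances. Degenerate
inputs are defined behaviour: empty sentences encode to `[CLS][SEP]` plus
padding, 0-epoch training returns the initialisation, one-class
evaluation marks rank metrics NaN, sequences shorter than 41 yield no
windows with a warning.

## Known limitations

* The `paper` preset is provided but not exercised: full-scale pretraining
  on millions of sentences is out of desk-scale reach, so published
  benchmark numbers are not reproduced here.
* Tokenizer vocabulary induction is frequency-based, not BPE/unigram-EM;
  for 6-mer DNA corpora this is behaviourally equivalent (whole words
  enter the vocabulary), but subword segmentations of rare natural-language
  words will differ from the original algorithms.
* ELECTRA uses sampled rather than generated corruption; XLNet omits
  two-stream attention (see Pretraining).
* The center-max filter frequently selects a window whose center is offset
  by one or two bases from a true site when the learned importance peak is
  slightly off-center; calls should be interpreted with single-base
  tolerance in mind.
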