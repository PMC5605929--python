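# Methods

## Task and model

ADR mention extraction is cast as sentence-level sequence labeling over
the tag set `{O, B-ADR, I-ADR}`.  The tagger is an encoder-decoder pair:

* **Encoder.**  Token representation = word embedding (lowercased
  lookup) ⊕ optional char-CNN feature vector (case-preserving, so
  orthographic shape survives the lowercased lookup).  The sequence
  passes through `L ∈ [1,4]` stacked bidirectional LSTM/GRU layers;
  each layer consumes the *concatenation* of the previous layer's
  forward and backward states (summing is the other defensible choice;
  concatenation keeps the directions distinguishable at the cost of
  doubling fan-in).  The outputs pass through inverted dropout and a
  linear dense layer with one output per tag.  Dropout is applied only
  at that point — between the recurrent stack and the dense projection —
  not inside the recurrence.
* **Decoder.**  Either an independent per-token softmax (baseline) or a
  linear-chain CRF (the joint model) over the dense scores.  The CRF
  adds a learned `|Y|×|Y|` transition matrix `A` (row = from-tag) and
  learned start/stop score vectors; the boundary vectors are the
  standard way to make the first/last transition well defined
  (equivalent to a virtual BOS/EOS tag, and strictly more general than
  dropping the boundary terms).

All CRF computation is in log space with log-sum-exp: the partition
function by the forward recursion, the NLL gradient by forward-backward
marginals (model marginals minus gold indicators), decoding by Viterbi
with ties broken to the lowest tag index so runs are reproducible.
Both exact-inference routines are `O(n·|Y|²)` and are tested against
exhaustive path enumeration.  Decoding can optionally be constrained to
the BIO grammar by `-inf` masks on `O→I-ADR` and `start→I-ADR`.

The whole network is trained by mini-batch Adam (β₁=0.9, β₂=0.999,
ε=1e-8, lr=0.001 unless overridden) on padded batches with explicit
length masks; padded positions contribute nothing to the loss, the
partition function, or the metrics.  The budget is a fixed number of
epochs with dev-best checkpointing (no patience-based early stop); one
integer seed drives parameter init, OOV embedding sampling, dropout
masks and batch shuffling.  Runs are bit-reproducible on a single
backend.

Gradients flow through a small in-repo reverse-mode autodiff engine
over numpy float64 arrays (`adrtag._autodiff`).  The CRF NLL enters the
tape as a custom node whose backward pass is the forward-backward
marginal computation — exact, not an autodiff of the recursion.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| hidden size | 100 / direction | community-standard for BiRNN taggers of this size |
| char embedding | 25-dim | ditto |
| char-CNN filters | widths (2,3,4) × 25 | covers prefix/suffix/stem n-grams |
| dropout | 0.5 | standard for RNN-output dropout |
| batch size | 128 | training protocol default |
| epochs | 100 max | fixed budget + dev-best checkpoint |
| word case | lower for lookup, preserved for chars | shape info lives in the char channel |
| optimizer | Adam, defaults | robust without per-task tuning |

The char-CNN convolution is **linear** before max-pooling (no
activation): pooled features feed a recurrent stack that supplies
nonlinearity, and the linear form makes the feature semantics
transparent (each filter's pooled value is the maximum of an affine
function of a character n-gram).

Word embeddings are read from word2vec text format.  Out-of-vocabulary
words are initialized uniformly from the `[min, max]` range of the
loaded embedding weights — matched to the partial-coverage regime the
tagger is used in, where ≈97% of corpus words have pretrained vectors.

## Corpus handling

* Offsets are 0-based half-open everywhere (the brat convention).
* Tokenization and sentence splitting are rule-based (whitespace split,
  edge-punctuation peeling; `[.!?]`-based sentence bounds), offset-true,
  and pluggable: any tokenizer that reports faithful character offsets
  can be substituted.  Offset fidelity is what makes span-level
  evaluation well defined.
* Overlapping ADR annotations are resolved by collapsing every group of
  transitively overlapping spans to the single longest continuous span
  covering the group; discontinuous brat spans are first collapsed to
  their covering interval.  Resolution is idempotent.  Only ADR spans
  participate — overlaps with other entity types are out of scope.
* BIO decoding repairs orphan `I-ADR` tags by opening a span there
  (`invalid="repair"`, the default), because softmax heads do emit
  invalid sequences and they must still be evaluated; a strict mode
  raises instead.
* A token belongs to a span if their character intervals intersect at
  all, which maximizes agreement with sub-token-boundary annotations.
* The 70/30 train/test split is at document (review) level, never
  sentence level, so no review leaks across the split.

## Evaluation

Exact mode counts boundary-identical spans with corpus-level (micro)
counts — the CoNLL convention; a per-sentence macro variant exists
behind a flag.  Partial mode gives each predicted term
`Σ overlap/|t_s|` precision credit and each gold term `Σ overlap/|t|`
recall credit (token counts), capped at 1 per term; P and R are
averaged per sentence and F is the harmonic mean of the averages.
Conventions for empty sentences: both sides empty → the sentence counts
(1.0, 1.0); a 0/0 on one side only (e.g. no predictions against
non-empty gold) is undefined and excluded from that side's average
while the defined side scores 0.  The cap matters only when gold terms
themselves overlap (impossible after resolution); it guards the P > 1
ambiguity that arises when one prediction intersects several gold terms.

## Synthetic corpus

The generator emulates what the tagger assumes about real review
corpora: short documents (default 625 documents × 4 sentences, giving a
2000/500 sentence split at 80/20) of templated sentences with 0-4
multi-word ADR phrases planted per sentence (`p_adr_per_slot = 0.7`)
from a ~70-phrase lexicon of real patient-reported reaction surface
forms.  Difficulty comes from `transition_noise_rate` (default 0.2;
0.35 in the head-comparison study): lexicon phrases also occur in
non-experience contexts where they are *not* annotated, so a dictionary
lookup has recall 1 but precision < 1 and the tagger must read context.
A toy embedding file covers 97% of the vocabulary.  Overlap injection
adds duplicate raw annotations with a recorded expected resolution.

What the generator does **not** model: grammar, misspellings, tokenizer
ambiguity, discontinuous or nested gold entities, class imbalance
beyond the slot probabilities, or lexical variation outside the
lexicon.  Passing tests on this corpus therefore demonstrate that the
machinery (codecs, inference, training loop, evaluation) is correct and
that the architecture can exploit context; they do not predict absolute
scores on real clinical or social-media text.

Study problem sizes were chosen to keep a full run on one CPU short:
the recovery experiment trains 2 layers × 100 hidden units on 2000
sentences for 12 epochs (the dev-best F1 saturates ≈1.0 well before
that); the head-comparison study trains 1 layer × 40 hidden units on
600 sentences for 12 epochs, 10 seeds per head — large enough that the
CRF/softmax ordering is stable, small enough to run in about a minute.

## Demographic term mining

Given per-review extracted terms and demographic tags, a term is
reported as distinctive for group *g* if it occurs in **more than four**
reviews of *g* (review-level counting: a term repeated inside one
review counts once; raw-occurrence counting is available) and its exact
normalized form (lowercase, whitespace collapse — no stemming, since
the rule is exact string match) never occurs in a review with a
different tag on the same dimension.  The "all authors" view applies
the threshold only.  For that view the threshold is the only filter by
construction; for group views the threshold is applied before the
exclusion, which cannot change the result since exclusion is
count-independent.

## Known limitations

* Pure-numpy training is single-threaded BLAS-bound; fine at the corpus
  sizes here, not meant for million-review corpora.
* The tokenizer is English-punctuation rule-based; no abbreviation
  handling in sentence splitting.
* Single entity type (ADR).  Multi-type tagging would need only a
  larger tag inventory but is untested.
* ADR normalization (mapping mentions to a terminology) is out of
  scope.
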