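# Methods

This note documents the modeling choices in `rctscreen`: what the
pipeline assumes, which parameters matter and why they have the defaults
they do, what the synthetic corpus does and does not emulate, and known
limitations.

## Data model and preprocessing

A citation is a title, an abstract (possibly empty), a tri-state
publication-type (PT) status — *present* (the record carries the MEDLINE
"Randomized Controlled Trial" publication type), *absent* (the record has
PT information but not that value), or *unknown* (no PT information at
all, e.g. a non-PubMed export) — and an optional gold label. The
present/absent/unknown distinction matters downstream: absence of the tag
on an indexed record is evidence *against* being an RCT, while absence of
the field is no evidence either way.

Tokenization lowercases and extracts maximal runs of Unicode
letters/digits of length ≥ 2; single characters and punctuation carry
almost no signal for this task and mostly add vocabulary noise. Stopwords
are removed against a pinned list of ~150 English function words shipped
in `data/stopwords.txt`; the list is versioned with the package so that
tokenization is reproducible. The token pattern and stopword list are
configurable through `TokenizerConfig`.

The vocabulary keeps the `max_size` most frequent training-corpus tokens
(default cap 12 500), ranked by descending frequency with lexicographic
tie-break so construction is deterministic and order-free. Index 0 is
reserved for padding and index 1 for out-of-vocabulary tokens; the linear
model simply ignores out-of-vocabulary tokens (no OOV feature), while the
CNN maps them to a learned OOV embedding.

RIS reading accepts both `TI`/`T1` (title) and `AB`/`N2` (abstract),
treats `PT`/`M3` as publication-type-bearing tags (case-insensitive match
on the phrase "randomized controlled trial"), preserves all other tags
verbatim for round-trip fidelity, warns on (rather than silently drops)
records with empty titles, and reports the byte offset of a record that
lacks its `ER` terminator.

## Linear classifier

Documents become sparse term-count vectors over the vocabulary;
optionally tf-idf-weighted counts (smoothed idf `log((1+N)/(1+df)) + 1`)
and/or a disjoint block of binary title-presence indicators. The shipped
default is raw unigram counts with neither option — the tuned operating
configuration for this task uses unigrams, and the extra features are
kept behind flags because they were part of the explored design space.

Training is hinge-loss SGD with L2 regularization (alpha 0.00092), 66
full passes, and class weights 12.4 (RCT) : 1.0, via scikit-learn's
`SGDClassifier` with its standard regularization-coupled learning-rate
schedule. Early stopping is disabled so the pass count is exact, and the
shuffle seed is explicit, making training bit-for-bit reproducible. The
model records the mean and sample SD of its training-set decision scores
for later normalization.

## Convolutional classifier

The architecture is the single-layer sentence-classification CNN: token
indices → embedding rows, banks of linear filters of widths 1/3/5 slide
over adjacent embeddings (stride 1, valid positions only; sequences
shorter than the widest filter are implicitly padded up to it), outputs
are rectified and max-pooled to one scalar per filter, the 3 × 150 pooled
scalars are concatenated, and a softmax layer yields the RCT probability.
The pooled dimension is independent of document length by construction.

Settings fixed by the tuned configuration: dropout 0.160 (applied to the
concatenated pooled vector only), max-norm 3.33 on each output-layer
class weight vector (re-projected after every optimizer step), class
weight 3.86, 2 epochs, vocabulary cap 12 500, no additional hidden
layers. Settings this implementation had to pin itself: Adam (learning
rate 0.001, batch 32), rectifier nonlinearity, embedding dimension 200
with N(0, 0.01²) initialization, maximum sequence length 400 tokens
(covers nearly all real abstracts while bounding memory), trainable
embeddings, and max-norm applied to the output layer only (the most
common convention for this architecture family). A word2vec-text-format
file can seed the embedding rows of matching tokens; no pretrained
embeddings are shipped.

The entire network — forward pass, backpropagation (argmax routing
through max-pooling, scatter-add into the embedding matrix; the padding
row is fixed at zero) and Adam — is plain numpy, so a single integer seed
fixes initialization, shuffling and dropout masks exactly.

`FAST_CNN` is a reduced preset for desk-scale work: embedding dimension
32, 64 filters per width, sequences capped at 200 tokens, with all
regularization settings unchanged. The 200-token cap was chosen to cover
the synthetic documents end to end (mean length ~165 tokens); truncating
below the document length discards planted signal tokens and is the main
way to cripple the CNN on these corpora.

## Class imbalance: balanced sampling and bagging

Each training subset contains every RCT plus `round(ratio × n_RCT)`
non-RCTs sampled uniformly without replacement (ratio 9.2 for the SVM,
6.0 for the CNN; capped with a warning if fewer negatives exist). This is
repeated with seeds `base_seed + k` to train `n_models` components
(default 25), whose consensus is the arithmetic mean of their scores.
Bagging mainly reduces the variance of the CNN: its held-out AUROC climbs
for the first ~6 components and is flat afterwards, which is why the fast
preset trains 7.

## Ensembling and hybrid routing

Member scores live on incompatible scales (unconstrained SVM decision
values, CNN probabilities, a 0/1 PT vote), so each member is z-normalized
by its training-set mean and sample SD and the ensemble score is the sum
of normalized members. The PT vote is treated symmetrically with the
model scores: its 0/1 training stream is normalized like any other (a
choice this package makes; any fixed positive scaling of one member
changes scores but not, with refitted statistics, the ranking).
Normalizer statistics are computed on the full training set.

Routing: a record with known PT status (present or absent) is scored by
the svm+cnn+pt ensemble — absence being an informative 0-vote — while a
record with no PT information falls back to the text-only svm+cnn
ensemble. The routed path is recorded per record.

## Evaluation and calibration

A prediction is positive at score ≥ threshold (the closed side matters
for calibration). Sensitivity, specificity and precision come from the
2×2 table, with explicit errors on zero denominators rather than silent
zeros; NNS = 1/precision. ROC curves group tied scores into one
threshold step; AUROC is the trapezoid area, which equals the
tie-corrected Mann-Whitney statistic exactly (property-tested). AUROC
confidence intervals use the DeLong structural-components variance with a
normal approximation, truncated to [0, 1]; a stratified-bootstrap utility
provides an independent variance cross-check. Paired differences in
proportions use an adjusted-Wald interval adding 0.5 to each discordant
cell (and 1 to n) — the exact adjustment variant is pinned here since
"modified Wald" names a family.

Threshold calibration targets a use case: given a sensitivity floor it
returns the *largest* threshold whose sensitivity meets the floor
(maximizing specificity subject to it), given a specificity floor the
*smallest* threshold whose specificity meets it. The presets encode a
0.985 sensitivity floor (systematic review) and a 0.975 specificity floor
(rapid review). In the Model/Results pipeline, calibration is performed
on the held-out split (default 20%, stratified); the full training set is
reserved for model fitting and normalizer statistics.

The screening-burden projection converts a filter's sensitivity and
specificity into expected corpus-scale counts, rounding expected values
to the nearest integer: `tp = round(sens × n_RCT)`,
`fp = round((1−spec) × n_non)`; precision is undefined (an error, not 0)
when nothing is retrieved.

## Synthetic corpus

The generator emulates exactly the structural properties the pipeline is
sensitive to: a minority positive class (prevalence default 0.016,
matching the RCT share of a large bibliographic database); four
trial-signal tokens with class-conditional occurrence probabilities
(defaults: "randomized" 0.90/0.05, "trial" 0.70/0.15, "randomly"
0.50/0.04, "placebo" 0.45/0.02 — the first pair being the canonical
strong-signal configuration, the rest chosen once as plausible weaker
signals), inserted at most once per document at a uniform position; a
Zipf(1.1) background vocabulary of 5 000 synthetic word types; titles of
5–15 tokens and abstracts of Poisson(150) tokens (minimum 10); and a PT
tag flipped with configurable sensitivity/specificity (defaults
0.937/0.976, the reported accuracy of the manually applied tag). One
seed fixes the corpus byte-for-byte.

What it deliberately does not emulate: natural-language syntax, topic
structure, correlated token occurrences, position effects (signal words
in titles vs abstracts), near-duplicate records, or label noise. Passing
tests on this corpus therefore demonstrate that the pipeline recovers a
planted lexical signal under realistic imbalance and tag noise — not
that it attains any particular accuracy on real bibliographic data,
where the signal is weaker and distributed across many correlated
features.

The reference experiment used throughout the tests and the acceptance
script is a 2 000-document corpus at prevalence 0.1 with the default
signal tokens, an 80/20 stratified split, the fast CNN preset with a
7-model CNN bag and a 10-model SVM bag. These sizes keep a full
train-and-evaluate cycle under a minute on one CPU while leaving all the
qualitative behavior (signal recovery, bagging plateau, ensemble
dominance) visible.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; component k of a bag uses `base_seed + k`.
- Vocabulary ties break lexicographically; ranking ties preserve input
  order (stable sort).
- Empty documents (all tokens stopworded) are an error at vectorization;
  the CLI drops such records with a logged count before scoring.
- Zero score variance in any normalizer member is an error naming the
  member (it would make z-scores undefined).
- A specificity floor is always attainable (the reject-all threshold has
  specificity 1); an unattainably high floor therefore cannot occur, but
  the reject-all operating point has undefined precision, reported as
  NaN rather than an error in calibration output.

## Known limitations

- The SVM's learning-rate schedule is scikit-learn's default
  regularization-coupled heuristic; the pass count and loss match the
  tuned configuration but per-step dynamics are implementation-specific.
- The CNN optimizer, batch size, nonlinearity and embedding dimension are
  pinned choices, not tuned values; no hyperparameter search utility is
  provided.
- Dense Adam states for the full embedding matrix make CNN training
  memory-proportional to vocabulary × embedding dimension; fine at the
  shipped caps, wasteful far beyond them.
- The bundled evaluation assumes binary gold labels; no support for
  crowd-consensus or probabilistic labels.
- RIS handling targets the common tag dialects (TI/T1, AB/N2, PT/M3);
  exotic exporter dialects may park fields in `extra_fields` rather than
  mapping them.
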