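# Methods

This note documents the models, the numerical choices, and the design
decisions behind `ohc-accept`, and states what the synthetic experiments
do and do not show.

## Problem and data model

In an online health-care community a patient posts a question and
several doctors answer.  An answer is *accepted* (positive class) when
the patient adopts it or inquires after it again; the other answers
under a responded question are negatives.  Questions with no patient
reaction carry no label information and are removed by
`filter_and_label`, as are records missing any of the nine tabular
attributes (patient age and gender; doctor title, reputation, patients
helped, gratitude count; answer character count, question-to-answer
delay, answer order).  Two resolutions the filtering makes explicit:

* A question whose answers are all negative is **kept** (all-negative
  groups still inform ranking); this situation is observable because an
  explicit 0/1 label on any sibling answer marks the question as
  responded even when no `patient_response` behaviour is recorded.
* Disease restriction is a generic filter on an optional `disease` tag,
  not hard-coded to any particular condition.

## Text preprocessing

Tokenization is a strategy interface.  The default splits on
whitespace, which is correct for the synthetic corpora and for
pre-segmented text.  For unsegmented Chinese text a forward
maximum-matching segmenter over a user-extendable lexicon is provided;
it is intentionally simple (greedy longest match) and is not a
reimplementation of a statistical segmenter — production users with
Chinese corpora should plug in their own tokenizer through the same
interface.

The vocabulary keeps tokens whose corpus frequency is at least
`min_count` (default 30; "below 30" is replaced, so a count of exactly
30 survives).  Everything else, and anything unseen, maps to UNK.  A
PAD index (always 0) supports batching; its embedding row is zero and
it is masked out of attention and the LSTM recurrence.

Embeddings (dimension 100 by default) come from one of three modes:
`train_word2vec` — an in-package skip-gram negative-sampling trainer
(window 5, 5 negatives, unigram^0.75 noise distribution, one
mini-batched SGD step per sentence); `load_pretrained` — word2vec text
format with seeded-random fallback for missing tokens; `random_init` —
seeded U(−0.5, 0.5) rows.  The uniform scale matters: vectors must have
O(1) norms to be usable directly as frozen LSTM inputs (a tiny
±0.5/d-style init, the usual *starting point* for word2vec training,
leaves the encoder effectively inputless).  Embeddings are frozen
during encoder training by default (`fine_tune_embeddings` enables
updates).

## Numerical features

Categorical attributes become one-hot blocks whose levels are collected
at fit time (gender 2, title 3, reputation 3 when all levels occur).
Continuous attributes are right-skewed counts and delays, transformed as
log(x + 1); the +1 offset keeps the zero minima of the delay and count
fields finite, and natural log is used.  Patient age is left raw by
default — age is bounded and not generally right-skewed — but the
transform is configurable per field.  Answer order is treated as
continuous with the log transform (configurable).  No standardisation is
applied beyond the log: the downstream boosted trees are invariant to
monotone rescaling.

## The co-attention encoder

Notation and shapes are in the README.  Choices that the formulation
leaves open, and how this implementation resolves them:

* **Softmax orientation.**  The attention matrices are normalised so
  that attention over the *attended* sequence sums to one: each column
  of `S_Q` (one per question word) is a distribution over answer
  positions, and each column of `S_A` (one per answer word) is a
  distribution over question positions.  This is the only orientation
  under which `C_Q = A S_Q` and `C_A = [Q; C_Q] S_A` are convex
  combinations of state vectors.  PAD positions receive exactly zero
  weight and are excluded from the normaliser.
* **`C_Q` semantics.**  `C_Q = A S_Q` is computed exactly as written;
  algebraically it is a summary of the *answer* states per question
  word even though it is often described as a question summary.  The
  tests pin the algebra, not the narration.
* **Fixed lengths with masks.**  Sequences are padded/truncated to
  `N` = `max_question_len` and `M` = `max_answer_len` (both default 64,
  head truncation, counted and logged).  The fixed `M` is what makes the
  MLP context variant's output a constant-length classifier input; its
  per-position scalars are zeroed at PAD columns.  A record that is
  empty after preprocessing is flagged; at inference it is represented
  by a single UNK token so outputs stay aligned with records.
* **LSTM details.**  Gate order (input, forget, cell, output), zero
  initial state, forget-gate bias 1, Xavier-uniform weights, seeded.
  PAD steps carry the hidden and cell state through unchanged, so the
  state at the last time step equals the state at the last real token.
  The two sequence LSTMs are separate by default; `share_qa_lstm` ties
  them.
* **Training.**  Adam (lr 0.001), batch size 100, state size 100,
  cross-entropy; inverted dropout (rate 0.5) on the context
  representation `h`; global-norm gradient clipping at 5.0.  An
  internal stratified 80/20 split is made inside `fit` (seeded): 80%
  trains the encoder, 20% is the held-out monitor used for early
  stopping (patience 3 epochs on held-out loss, best-epoch parameters
  restored) and for the reported held-out accuracy.  The epoch budget
  defaults to 20; the test suite and the acceptance script use the same
  budget and stop early in practice.
* **Numerics.**  Parameters and activations are single precision by
  default (`precision="double"` is used by the oracle-equivalence and
  gradient-check tests).  Softmaxes subtract the per-column maximum
  before exponentiation.  The recurrence is a single fused
  reverse-mode op with hand-written backpropagation through time,
  validated against central finite differences; everything else
  composes small taped operations.

## Fusion and evaluation

`h_i = (h_i^text, h_i^num)` — text block first, then numeric — feeds a
gradient-boosting classifier (scikit-learn's, 100 estimators, depth 3,
learning rate 0.1 by default; xgboost and lightgbm are pluggable
backends behind the same configuration).  Evaluation follows the
three-way protocol — textual only, numerical only, all — on *identical*
folds: stratified 5-fold cross-validation, grouped by question so that
answers to the same question never straddle a train/test boundary
(grouping is on by default and configurable).  The classifier
cross-validates on the encoder's held-out 20% — records the encoder
never trained on — so textual features are not memorised labels; the
encoder is trained once, features are fixed across folds.  Metrics are
recall, precision, accuracy, F1 and rank-based (Mann–Whitney, midrank
ties) ROC AUC, reported fold-wise as mean ± std.  ROC axes use the
standard orientation (TP rate = TP/(TP+FN) vertical, FP rate =
FP/(FP+TN) horizontal).  Thresholded metrics use 0.5 by default, with
score = threshold counted as positive; zero-denominator metrics are
defined as 0 with a warning.

## Synthetic corpus generator

The generator emulates the structure of a private OHC corpus so that
every stage is testable without any download.  Study-level conditions
are its defaults: 2.36 answers per question (1 + Poisson), 60% positive
rate, question/answer token-length means 43 / 55 (geometric with a
minimum of 3) — the token analogue of the emulated corpus's character
means of 73.6 / 94.0 at ≈1.7 Chinese characters per word — and tabular
attributes
drawn inside the documented ranges (age 0–98 truncated normal; doctor
patients-helped and gratitude log-normal with caps 406 342 / 13 883;
answer characters ≈ 1.7 × tokens clipped to 12–734; delay log-normal
capped at 8005.37 s; order 1..k).  One patient per question and a
doctor pool of ≈0.22 × questions keep participant counts in realistic
proportion.

Text is generated from disjoint topic blocks (20 topics × 30 token
types over a 600-token vocabulary, Zipf weights within a topic).  A
question draws one topic; each answer mixes the question's topic
distribution (weight = relevance r ~ U(0.05, 0.95)) with a uniform
background.  The planted textual mechanism is the overlap `o` — the
fraction of answer tokens present in the question — chosen because the
co-attention encoder can detect it by construction.  Labels follow

    η = α + β_text·o + β_num·x_num + N(0, σ),   y ~ Bernoulli(logistic(η))

with x_num the standardised log-scale doctor/answer covariates,
defaults β_text = 5, β_num = (0.8, 0.4, −0.5, −0.8), σ = 0.5 — a strong
but noisy textual effect (overlap alone gives AUC ≈ 0.75) and numeric
effects of mixed sign.  α is calibrated by bisection so the expected
positive rate matches the target.  The latent truth (topic, r, o,
x_num, η, p) is returned for parameter-recovery tests.  Optional
corruption modes inject missing tabular values and unresponded
questions to exercise the filter.

What the generator does **not** emulate: real clinical language (tokens
are synthetic symbols; no syntax, negation or paraphrase), label noise
structure beyond the logistic model, per-question exclusivity of
acceptance (labels are independent Bernoulli draws given η), and any
particular disease mix (the disease tag is cosmetic, 90/10 by default).
Passing tests therefore demonstrate that the machinery — filtering,
encoding, attention algebra, optimisation, fusion, evaluation — behaves
correctly and that the encoder can extract a planted lexical-overlap
signal; they do not certify performance on real OHC text.

## Problem sizes used in tests and the acceptance script

Encoder learnability experiments use 1000-question corpora (~2300
records), word2vec dim 100, state size 100, epoch budget 20 with
patience 3; the three-way fusion comparison uses 2000 questions so the
non-held-out cross-validation set (~940 records) gives stable per-fold
AUCs.  Unit tests use smaller state sizes and corpora.  Parameter
recovery uses ~50 000 records.  The pipeline-determinism check runs the
CLI end-to-end twice at 150 questions, dimension 32.  These sizes were
chosen as the smallest at which the statistical properties under test
are stable.

## Known limitations

* The pure-numpy encoder is single-threaded and CPU-bound; it is meant
  for research-scale corpora (10³–10⁴ pairs), not the millions of
  records of a production OHC.
* The max-matching Chinese segmenter is a baseline adapter, not a
  competitive segmenter.
* The skip-gram trainer is compact rather than tuned; for real corpora,
  pre-trained embeddings via `load_pretrained` are preferable.
* Head truncation at N/M tokens loses tail content of very long texts.
* The encoder's held-out accuracy on synthetic corpora sits well below
  the overlap-oracle ceiling; closing that gap (more epochs, larger
  corpora, fine-tuned embeddings) trades runtime for fidelity.
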