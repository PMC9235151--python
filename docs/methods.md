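# Methods

## The consultation model

An online consultation opens with a patient's free-text *initial
description* `x`. A doctor reads it, asks follow-up questions until
confident, and assigns a disease label. `consultprompts` models the three
ingredients of that loop:

1. **Diagnosis function `f`.** A probabilistic multiclass text classifier
   mapping consultation text to a distribution `y` over the `m` diseases.
   `f` is trained on *complete information* — the concatenation of each
   record's initial description and doctor-patient conversation — so that,
   like a doctor who has already heard the answers, it knows which terms
   discriminate between diseases. At prediction time it sees only `x`
   (optionally extended with prompted terms).
2. **Uncertainty gate.** The Shannon entropy `H(y) = -Σ_j y_j ln y_j` of the
   predicted distribution, compared against a threshold `τ` calibrated as
   the mean entropy of `f`'s predictions over the *training-fold initial
   descriptions*. A prediction more uncertain than the average training
   self-description triggers prompting. Margin (top minus second
   probability) and confidence (top probability minus `1/m`) are supported
   as alternative measures; both are negated when used as uncertainty
   scores so that larger always means more uncertain, which keeps the
   gate's strict `score > τ` comparison uniform. Entropy uses the natural
   log; the base rescales `H` and `τ` jointly, so gating decisions are
   base-invariant.
3. **Elicitation function `g`.** Given `x`, scores each term of a fixed
   *prompt vocabulary* by its predicted utility; the top `q` terms are shown
   to the patient (here: appended to `x`, emulating a patient who mentions
   them), and `f` re-predicts on the extended text.

## Prompt vocabulary

The vocabulary is the top `k` (default 100) conversation terms by a
corpus-level TFIDF weight computed over the training-fold conversations:

    weight(t) = tf(t) · ln((1 + N) / (1 + df(t)))

with `tf` the total term count across conversations, `df` the number of
conversations containing the term, and `N` the number of records. The
smoothed idf sends terms present in every conversation to weight zero, so
ubiquitous boilerplate cannot outrank discriminative terms. Ties break
lexicographically; a corpus with fewer than `k` distinct conversation terms
yields all of them with a warning. Any fixed, documented variant of TFIDF
serves the purpose here; this one was chosen for determinism and for having
an exactly hand-computable toy oracle.

## Elicitation strategies

* **none** — no prompting; the baseline.
* **learned** — `k` independent binary classifiers, one per vocabulary
  term, sharing one bag-of-words featurization of `x`. The training label
  for term `z_l` on record `i` is `1` iff appending `z_l` to the initial
  description *strictly* raises `f`'s probability of the record's true
  disease (equivalently `⟨y_i, f(x_i + z_l)⟩ > ⟨y_i, f(x_i)⟩` for one-hot
  `y_i`). A term whose labels are all equal gets a constant scorer. All
  training records are used, including those `f` already classifies
  confidently.
* **certainty** — score each term by the *negated* uncertainty of
  `f(x + z_l)`: terms that make the prediction most certain rank top.
* **uncertainty** — the exact elementwise negation of the certainty
  scores, i.e. the reversed ranking (the uncertainty-sampling heuristic
  from active learning).

Top-`q` selection breaks score ties by vocabulary order, which is itself
deterministic. The update operation is a plain append: terms already
present in `x` are appended again (an optional flag could skip them, but
the unconditional append is the default because it is what the batched
evaluation path and the brute-force oracles assume). Certainty/uncertainty
scoring costs `k` forward evaluations of `f` per document; they are batched
through one featurization pass with results identical to one-at-a-time
evaluation.

## Classifier choices

Both `f` and the per-term scorers default to bag-of-words (raw token
counts) + L2-regularized multinomial logistic regression (`C = 1.0`,
`lbfgs`, `max_iter = 1000`). Raw counts rather than TFIDF are used for `f`
because the featurization of the diagnosis classifier and the weighting of
the prompt vocabulary are independent decisions; TFIDF is reserved for the
vocabulary where it defines term importance. Tokenization is a pluggable
interface whose default lowercases and splits on Unicode
whitespace/punctuation boundaries — adequate for the synthetic vocabulary
and English text; CJK segmenters can be registered for real Chinese
corpora. Transformer backends are out of scope; the backend registry
(`register_backend`) is the extension point.

## Evaluation protocol

Stratified 5-fold cross-validation. Classes with fewer records than the
fold count cannot be stratified and are filtered out first (default
`min_count = n_folds`). Per fold, *everything* learned — `f`, `τ`, the
vocabulary, and `g` — is refit on the training fold alone; this is the only
leakage-free reading of the protocol, and a dedicated test verifies that
perturbing test-fold conversations changes no trained artifact. Metrics
are multiclass top-1 accuracy, macro-averaged one-vs-rest F, AUC
(pairwise Wilcoxon–Mann–Whitney with the standard 0.5 tie convention),
MCC, and mean prediction entropy; macro averages weight all classes
equally. Degenerate-class conventions: F and MCC of a class with a zero
denominator are 0 (classes absent from a fold are penalized); AUC of a
class without both positives and negatives is undefined and skipped with a
warning, reducing the macro denominator. Aggregates are arithmetic means
over folds. The `gate="always"` mode (default in experiments) prompts
every test document; `gate="threshold"` prompts only documents whose
prediction exceeds `τ` and is the deployment workflow.

Seeding: one master seed feeds a `numpy` `SeedSequence`; derived child
seeds (one per fold plus one for the fold shuffle, all `< 2^31`) drive
every stochastic fit, making the whole sweep bit-reproducible.

## Synthetic corpus generator

The generator emulates the structural premise of prompting: each disease
has a `signature_size`-term signature (pairwise disjoint across diseases);
each signature term is revealed in the initial description with probability
`reveal_prob` (default 0.3), otherwise it appears in the conversation with
probability `conversation_prob` (default 0.9); `background_len` (default 8)
uninformative tokens drawn from a shared `background_size`-term pool
(default 50) pad each description; class frequencies follow
`P(rank r) ∝ r^(-class_skew)` (default 1, mirroring the heavy skew of real
consultation corpora). Defaults give a corpus where complete information is
nearly perfectly separable while initial descriptions are not — the
condition under which elicitation is meaningful. `oracle_best_prompts`
returns a disease's signature set, an exact ground truth for testing
elicitation. An optional `shared_terms` knob adds symptoms common to
adjacent disease pairs.

What the generator does **not** emulate: natural clinical language, symptom
co-occurrence structure, misspellings, negation, or doctors' questioning
order. Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline under its stated assumptions, not performance
on real consultation text.

A structural consequence of disjoint signatures worth knowing: a single
revealed signature term already identifies the disease, so the diagnosis
model's errors on initial descriptions concentrate entirely on
descriptions that reveal *no* signature term. For those, no
context-conditional elicitation can beat the class prior — which caps how
much any prompting strategy can raise accuracy on this construction, even
though it reduces prediction entropy dramatically. Overlapping signatures
(`shared_terms > 0`) create the partial-evidence regime where prompting
has more accuracy headroom.

## Numerical conventions

* `0 · ln 0 ≡ 0` in entropy; probabilities validated to sum to 1 within
  1e-9.
* Argmax ties (predicted label) resolve to the first label in the
  lexicographically fixed label order.
* The uncertainty gate is strict (`> τ`).
* Elicitation labels use strict inequality, so an out-of-vocabulary term
  (no effect on `f`) is labelled 0.
* Model persistence is a versioned JSON archive (label set, vocabulary,
  weights, tokenizer spec); JSON float round-tripping preserves
  predictions bit-for-bit.

## Problem sizes

The standard study conditions used by the test suite and
`scripts/acceptance.py` are `m = 5` diseases, `n = 500` records,
`signature_size = 4`, 5 folds, `q = 3` prompts — large enough for stable
fold averages on a single CPU in seconds, small enough to keep the full
suite fast. Unit tests use smaller corpora (`n` = 90–200).

## Known limitations

* Word-level prompts, not natural-language questions; the append update
  ignores syntax.
* The default tokenizer treats an unsegmented CJK sentence as one token;
  supply a segmenting tokenizer for real Chinese corpora.
* Macro-AUC is silently sensitive to which classes are scorable in small
  folds (warned, denominator reduced).
* Accuracy gains from prompting depend on the corpus offering partial
  evidence that prompts can complete; see the generator note above.
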