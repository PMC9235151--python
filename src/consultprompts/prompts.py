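"""Prompt vocabulary, elicitation strategies, and the consult workflow.

The prompt vocabulary is the set of k conversation terms most likely to
carry diagnostic information, ranked by a corpus-level TFIDF weight over the
training-fold conversations.  Given a patient's initial description x, an
elicitation strategy scores every vocabulary term by its predicted utility:

``learned``
    k independent binary classifiers, one per term.  The training label for
    term z_l on record i is 1 iff appending z_l to the initial description
    strictly raises the diagnosis model's probability of the true disease —
    i.e. the term would move the "simulated doctor" toward the diagnosis the
    real doctor eventually made.
``certainty``
    Rank terms so that appending them yields the *least* uncertain
    prediction (heuristic: chase certainty).
``uncertainty``
    The exact reverse ranking (heuristic: chase uncertainty, as in
    uncertainty sampling for active learning).
``none``
    No prompting; the bare prediction on x.

``consult`` ties it together: predict on x; if the prediction is uncertain
(or the gate is set to always prompt), score terms, select the top q, append
them to x, and re-predict.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Corpus, TokenizerSpec, get_tokenizer
from .diagnosis import DiagnosisModel, DiseaseDistribution
from .uncertainty import UncertaintyConfig, is_uncertain, uncertainty_score

__all__ = [
    "PromptVocabulary",
    "PromptScores",
    "ElicitationLabels",
    "ElicitationModel",
    "STRATEGIES",
    "build_prompt_vocabulary",
    "build_elicitation_labels",
    "fit_elicitation",
    "score_learned",
    "score_certainty",
    "score_uncertainty",
    "select_prompts",
    "apply_prompts",
    "consult",
    "ConsultResult",
    "save_elicitation",
    "load_elicitation",
]

STRATEGIES = ("none", "learned", "certainty", "uncertainty")

DEFAULT_VOCABULARY_SIZE = 100  # k: cap on the prompt vocabulary


@dataclass(frozen=True)
class PromptVocabulary:
    """Ordered prompt terms (descending TFIDF weight, lexicographic tie-break)."""

    terms: tuple[str, ...]
    tfidf_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.tfidf_weights, dtype=float)
        object.__setattr__(self, "tfidf_weights", w)
        if len(self.terms) < 1:
            raise ValueError("prompt vocabulary must contain at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("prompt vocabulary terms must be unique")
        if w.shape != (len(self.terms),):
            raise ValueError("weights must align with terms")

    @property
    def k(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class PromptScores:
    """Per-term utility scores aligned to a PromptVocabulary (higher = prompt)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if not np.all(np.isfinite(s)):
            raise ValueError("prompt scores must be finite")


@dataclass(frozen=True)
class ElicitationLabels:
    """n x k binary matrix: does appending term l help record i's true disease?"""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("label matrix must be 2-dimensional")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        object.__setattr__(self, "matrix", m.astype(np.int8))


# ---------------------------------------------------------------------------
# Prompt vocabulary (TFIDF over training conversations)
# ---------------------------------------------------------------------------

def build_prompt_vocabulary(
    corpus: Corpus,
    k: int = DEFAULT_VOCABULARY_SIZE,
    tokenizer: TokenizerSpec | None = None,
) -> PromptVocabulary:
    """Top-k conversation terms by corpus-level TFIDF weight.

    The document collection is the conversations of ``corpus`` (use the
    training fold only).  The weight of a term is

        weight(t) = tf(t) * ln((1 + N) / (1 + df(t)))

    where tf(t) is the total count of t across all conversations, df(t) the
    number of conversations containing t, and N the number of records.  The
    smoothed idf sends terms present in every conversation to weight 0, so
    ubiquitous boilerplate never outranks discriminative terms.  Ties are
    broken lexicographically.  If fewer than k distinct terms exist, all are
    returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tok = get_tokenizer(tokenizer or TokenizerSpec())
    n_docs = len(corpus.records)
    tf: Counter[str] = Counter()
    df: Counter[str] = Counter()
    for record in corpus.records:
        tokens = tok(record.conversation)
        tf.update(tokens)
        df.update(set(tokens))
    if not tf:
        raise ValueError("no conversation terms available to build a vocabulary")
    weights = {
        term: tf[term] * math.log((1 + n_docs) / (1 + df[term])) for term in tf
    }
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} distinct conversation terms available; "
            f"requested k={k}", stacklevel=2,
        )
    top = ranked[:k]
    return PromptVocabulary(
        terms=tuple(t for t, _ in top),
        tfidf_weights=np.array([w for _, w in top]),
    )


# ---------------------------------------------------------------------------
# Learned elicitation
# ---------------------------------------------------------------------------

def build_elicitation_labels(
    model: DiagnosisModel,
    corpus: Corpus,
    vocab: PromptVocabulary,
) -> ElicitationLabels:
    """Label each (record, term) pair by whether the term helps diagnosis.

    Entry (i, l) is 1 iff the probability of record i's true disease under
    f(x_i + z_l) strictly exceeds that under f(x_i), where x_i is the
    initial description and z_l the l-th prompt term.  ``model`` must be the
    diagnosis function fitted on the same training fold as ``corpus``.
    """
    ids = [r.initial_description for r in corpus.records]
    label_index = {lab: j for j, lab in enumerate(model.label_set)}
    true_cols = np.array([label_index[r.disease] for r in corpus.records])
    rows = np.arange(len(ids))
    base = model.predict_proba_batch(ids)[rows, true_cols]
    matrix = np.zeros((len(ids), vocab.k), dtype=np.int8)
    for l, term in enumerate(vocab.terms):
        prompted = model.predict_proba_batch([f"{x} {term}" for x in ids])
        matrix[:, l] = prompted[rows, true_cols] > base
    return ElicitationLabels(matrix=matrix)


class _ConstantScorer:
    """Scorer for a term whose training labels are all 0 or all 1."""

    def __init__(self, value: float) -> None:
        self.value = float(value)

    def predict_proba_positive(self, X) -> np.ndarray:
        return np.full(X.shape[0], self.value)


class _LogRegScorer:
    def __init__(self, clf: LogisticRegression) -> None:
        self._clf = clf
        # column of the positive class in predict_proba
        self._pos_col = int(np.where(clf.classes_ == 1)[0][0])

    def predict_proba_positive(self, X) -> np.ndarray:
        return self._clf.predict_proba(X)[:, self._pos_col]


class ElicitationModel:
    """The learned elicitation function g: k per-term binary scorers.

    All scorers share one bag-of-words featurization of the initial
    description; each outputs the probability that prompting its term would
    raise the true-disease probability.
    """

    def __init__(
        self,
        vocabulary: PromptVocabulary,
        vectorizer: CountVectorizer,
        scorers: Sequence[_ConstantScorer | _LogRegScorer],
    ) -> None:
        if len(scorers) != vocabulary.k:
            raise ValueError("one scorer per vocabulary term is required")
        self.vocabulary = vocabulary
        self._vectorizer = vectorizer
        self._scorers = list(scorers)

    def score_batch(self, texts: Sequence[str]) -> np.ndarray:
        X = self._vectorizer.transform(texts)
        out = np.empty((len(texts), self.vocabulary.k))
        for l, scorer in enumerate(self._scorers):
            out[:, l] = scorer.predict_proba_positive(X)
        return out

    def score(self, text: str) -> PromptScores:
        return PromptScores(scores=self.score_batch([text])[0])


def fit_elicitation(
    corpus_ids: Sequence[str],
    labels: ElicitationLabels,
    vocab: PromptVocabulary,
    hyperparams: Mapping[str, object] | None = None,
    seed: int = 0,
    tokenizer: TokenizerSpec | None = None,
) -> ElicitationModel:
    """Fit g: one L2 logistic regression per prompt term on shared BOW features.

    ``corpus_ids`` are the training-fold initial descriptions, row-aligned
    with ``labels``.  A term whose labels are all 0 (or all 1) gets a
    constant scorer at that value.  Deterministic given ``seed``.
    """
    hp = {"C": 1.0, "max_iter": 1000, **dict(hyperparams or {})}
    mat = labels.matrix
    if mat.shape != (len(corpus_ids), vocab.k):
        raise ValueError(
            f"label matrix of shape {mat.shape} does not match "
            f"{len(corpus_ids)} documents x {vocab.k} terms"
        )
    vectorizer = CountVectorizer(
        tokenizer=get_tokenizer(tokenizer or TokenizerSpec()),
        token_pattern=None,
        lowercase=False,
    )
    X = vectorizer.fit_transform(list(corpus_ids))
    scorers: list[_ConstantScorer | _LogRegScorer] = []
    for l in range(vocab.k):
        y = mat[:, l].astype(int)
        if y.min() == y.max():
            scorers.append(_ConstantScorer(float(y[0])))
            continue
        clf = LogisticRegression(
            C=float(hp["C"]), max_iter=int(hp["max_iter"]),
            solver="lbfgs", random_state=seed,
        )
        clf.fit(X, y)
        scorers.append(_LogRegScorer(clf))
    return ElicitationModel(vocabulary=vocab, vectorizer=vectorizer, scorers=scorers)


# ---------------------------------------------------------------------------
# Elicitation persistence (JSON archive mirroring the diagnosis model's)
# ---------------------------------------------------------------------------

def save_elicitation(model: ElicitationModel, path) -> None:
    import json
    from pathlib import Path

    scorers = []
    for s in model._scorers:
        if isinstance(s, _ConstantScorer):
            scorers.append({"kind": "constant", "value": s.value})
        else:
            clf = s._clf
            scorers.append({
                "kind": "logreg",
                "classes": clf.classes_.tolist(),
                "coef": clf.coef_.tolist(),
                "intercept": clf.intercept_.tolist(),
            })
    payload = {
        "schema_version": 1,
        "vocabulary": {
            "terms": list(model.vocabulary.terms),
            "tfidf_weights": model.vocabulary.tfidf_weights.tolist(),
        },
        "bow_vocabulary": {t: int(i) for t, i in model._vectorizer.vocabulary_.items()},
        "tokenizer": {"name": "whitespace", "parameters": {}},
        "scorers": scorers,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_elicitation(path) -> ElicitationModel:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != 1:
        raise ValueError(f"unsupported elicitation schema {payload.get('schema_version')}")
    vocab = PromptVocabulary(
        terms=tuple(payload["vocabulary"]["terms"]),
        tfidf_weights=np.array(payload["vocabulary"]["tfidf_weights"]),
    )
    spec = TokenizerSpec(name=payload["tokenizer"]["name"],
                         parameters=payload["tokenizer"]["parameters"])
    vectorizer = CountVectorizer(
        tokenizer=get_tokenizer(spec), token_pattern=None, lowercase=False,
        vocabulary={t: int(i) for t, i in payload["bow_vocabulary"].items()},
    )
    vectorizer._validate_vocabulary()
    scorers: list[_ConstantScorer | _LogRegScorer] = []
    for s in payload["scorers"]:
        if s["kind"] == "constant":
            scorers.append(_ConstantScorer(s["value"]))
        else:
            clf = LogisticRegression()
            clf.classes_ = np.array(s["classes"])
            clf.coef_ = np.array(s["coef"], dtype=float)
            clf.intercept_ = np.array(s["intercept"], dtype=float)
            scorers.append(_LogRegScorer(clf))
    return ElicitationModel(vocabulary=vocab, vectorizer=vectorizer, scorers=scorers)


# ---------------------------------------------------------------------------
# Strategy scoring
# ---------------------------------------------------------------------------

def score_learned(g: ElicitationModel, x: str) -> PromptScores:
    """Per-term probability that prompting the term helps, under the learned g."""
    return g.score(x)


def _appended_uncertainties(
    f: DiagnosisModel, x: str, vocab: PromptVocabulary, measure: str
) -> np.ndarray:
    texts = [f"{x} {term}" for term in vocab.terms]
    proba = f.predict_proba_batch(texts)
    return np.array([uncertainty_score(row, measure) for row in proba])


def _measure_name(measure: UncertaintyConfig | str | None) -> str:
    if measure is None:
        return "entropy"
    if isinstance(measure, UncertaintyConfig):
        return measure.measure
    return measure


def score_certainty(
    f: DiagnosisModel,
    x: str,
    vocab: PromptVocabulary,
    measure: UncertaintyConfig | str | None = None,
) -> PromptScores:
    """Negated post-append uncertainty: terms that make f most certain rank top."""
    u = _appended_uncertainties(f, x, vocab, _measure_name(measure))
    return PromptScores(scores=-u)


def score_uncertainty(
    f: DiagnosisModel,
    x: str,
    vocab: PromptVocabulary,
    measure: UncertaintyConfig | str | None = None,
) -> PromptScores:
    """Post-append uncertainty itself: the exact reverse of ``score_certainty``."""
    u = _appended_uncertainties(f, x, vocab, _measure_name(measure))
    return PromptScores(scores=u)


def select_prompts(scores: PromptScores, vocab: PromptVocabulary, q: int) -> list[str]:
    """The q highest-scoring terms, ties broken by vocabulary order."""
    if not 1 <= q <= vocab.k:
        raise ValueError(f"q must lie in [1, {vocab.k}], got {q}")
    order = np.argsort(-scores.scores, kind="stable")
    return [vocab.terms[i] for i in order[:q]]


def apply_prompts(x: str, terms: Sequence[str]) -> str:
    """Append the prompt terms to x, space-separated; no terms leaves x unchanged."""
    if not terms:
        return x
    return " ".join([x, *terms])


# ---------------------------------------------------------------------------
# Consult workflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsultResult:
    distribution: DiseaseDistribution
    label: str
    applied_terms: tuple[str, ...]


def consult(
    f: DiagnosisModel,
    strategy: str,
    x: str,
    config: UncertaintyConfig | None = None,
    q: int = 3,
    gate: str = "always",
    g: ElicitationModel | None = None,
    vocab: PromptVocabulary | None = None,
) -> ConsultResult:
    """One uncertainty-gated consultation round.

    Predict y = f(x).  If ``strategy`` is ``none``, or ``gate`` is
    ``threshold`` and y is not uncertain, return y as-is.  Otherwise score
    the vocabulary under the strategy, select the top q terms, append them
    to x, and return f(x + prompts) together with the applied terms.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    if gate not in ("threshold", "always"):
        raise ValueError(f"gate must be 'threshold' or 'always', got {gate!r}")
    base = f.predict_proba(x)
    if strategy == "none":
        return ConsultResult(base, base.argmax_label(), ())
    if gate == "threshold":
        if config is None:
            raise ValueError("gate='threshold' requires a calibrated UncertaintyConfig")
        if not is_uncertain(base, config):
            return ConsultResult(base, base.argmax_label(), ())
    if strategy == "learned":
        if g is None:
            raise ValueError("learned strategy requires a fitted elicitation model")
        vocab = g.vocabulary
        scores = score_learned(g, x)
    else:
        if vocab is None:
            raise ValueError(f"{strategy} strategy requires a prompt vocabulary")
        scorer = score_certainty if strategy == "certainty" else score_uncertainty
        scores = scorer(f, x, vocab, config)
    terms = select_prompts(scores, vocab, min(q, vocab.k))
    prompted = f.predict_proba(apply_prompts(x, terms))
    return ConsultResult(prompted, prompted.argmax_label(), tuple(terms))
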