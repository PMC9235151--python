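"""The diagnosis function f: a probabilistic multiclass text classifier.

f is trained on *complete information* (initial description + conversation)
so that, like a doctor who has already heard the answers, it knows which
terms discriminate between diseases.  At consultation time it is applied to
the initial description alone, optionally extended with prompted terms.

The default backend is a bag-of-words multinomial logistic regression with
L2 regularization.  Alternative backends (e.g. transformer classifiers) can
be registered through :func:`register_backend`; they must expose the same
fit signature and return a :class:`DiagnosisModel`-compatible object.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Corpus, TokenizerSpec, complete_info, get_tokenizer

__all__ = [
    "DiseaseDistribution",
    "DiagnosisModel",
    "fit_diagnosis",
    "register_backend",
    "save_model",
    "load_model",
]

_SCHEMA_VERSION = 1

# fixed defaults for the logistic-regression backend; overridable via hyperparams
_DEFAULT_HYPERPARAMS = {"C": 1.0, "max_iter": 1000, "binary_counts": False}


@dataclass(frozen=True)
class DiseaseDistribution:
    """A probability distribution over the disease label set.

    ``probabilities[j]`` is the predicted probability of ``labels[j]``;
    entries are non-negative and sum to 1 (within 1e-9).
    """

    labels: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (len(self.labels),):
            raise ValueError(
                f"probability vector of length {p.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")

    @property
    def m(self) -> int:
        return len(self.labels)

    def probability_of(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])

    def argmax_label(self) -> str:
        """Most probable disease; ties resolve to the first label in order."""
        return self.labels[int(np.argmax(self.probabilities))]


class DiagnosisModel:
    """A fitted diagnosis function: featurizer + multiclass probabilistic model."""

    def __init__(
        self,
        label_set: tuple[str, ...],
        vectorizer: CountVectorizer,
        classifier: LogisticRegression,
        tokenizer: TokenizerSpec,
        hyperparams: Mapping[str, object],
    ) -> None:
        self.label_set = tuple(label_set)
        self._vectorizer = vectorizer
        self._classifier = classifier
        self.tokenizer = tokenizer
        self.hyperparams = dict(hyperparams)
        if tuple(classifier.classes_) != self.label_set:
            raise ValueError("classifier class order does not match label_set")

    def predict_proba_batch(self, texts: Sequence[str]) -> np.ndarray:
        """(n, m) matrix of predicted disease probabilities, rows sum to 1."""
        X = self._vectorizer.transform(texts)
        return self._classifier.predict_proba(X)

    def predict_proba(self, text: str) -> DiseaseDistribution:
        """Predicted disease distribution for one text.

        Out-of-vocabulary tokens contribute nothing; a text with no known
        tokens yields the intercept-only (prior-like) prediction.
        """
        row = self.predict_proba_batch([text])[0]
        return DiseaseDistribution(labels=self.label_set, probabilities=row)

    def predict_label(self, text: str) -> str:
        return self.predict_proba(text).argmax_label()


def _make_tokenizer_callable(spec: TokenizerSpec) -> Callable[[str], list[str]]:
    return get_tokenizer(spec)


def _fit_bow_logreg(
    corpus: Corpus,
    tokenizer: TokenizerSpec,
    hyperparams: Mapping[str, object],
    seed: int,
) -> DiagnosisModel:
    hp = {**_DEFAULT_HYPERPARAMS, **dict(hyperparams or {})}
    docs = [complete_info(r) for r in corpus.records]
    y = [r.disease for r in corpus.records]
    vectorizer = CountVectorizer(
        tokenizer=_make_tokenizer_callable(tokenizer),
        token_pattern=None,
        lowercase=False,
        binary=bool(hp["binary_counts"]),
    )
    X = vectorizer.fit_transform(docs)
    clf = LogisticRegression(
        C=float(hp["C"]),
        max_iter=int(hp["max_iter"]),
        solver="lbfgs",
        random_state=seed,
    )
    clf.fit(X, y)
    return DiagnosisModel(
        label_set=corpus.label_set,
        vectorizer=vectorizer,
        classifier=clf,
        tokenizer=tokenizer,
        hyperparams=hp,
    )


_BACKENDS: dict[str, Callable[..., DiagnosisModel]] = {"bow_logreg": _fit_bow_logreg}


def register_backend(name: str, fitter: Callable[..., DiagnosisModel]) -> None:
    """Register a classifier backend; ``fitter(corpus, tokenizer, hyperparams, seed)``."""
    _BACKENDS[name] = fitter


def fit_diagnosis(
    corpus: Corpus,
    backend: str = "bow_logreg",
    tokenizer: TokenizerSpec | None = None,
    hyperparams: Mapping[str, object] | None = None,
    seed: int = 0,
) -> DiagnosisModel:
    """Fit the diagnosis function on the complete information of ``corpus``.

    Each training document is ``complete_info(record)`` — the concatenation
    of the initial description and the conversation.  Deterministic given
    ``seed``.
    """
    try:
        fitter = _BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown diagnosis backend {backend!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    return fitter(corpus, tokenizer or TokenizerSpec(), hyperparams or {}, seed)


# ---------------------------------------------------------------------------
# Persistence — a self-describing JSON archive (text-only, versioned)
# ---------------------------------------------------------------------------

def save_model(model: DiagnosisModel, path: str | Path) -> None:
    """Serialize a bag-of-words diagnosis model to a JSON archive."""
    clf = model._classifier
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "kind": "bow_logreg",
        "label_set": list(model.label_set),
        "tokenizer": {"name": model.tokenizer.name,
                      "parameters": dict(model.tokenizer.parameters)},
        "hyperparams": model.hyperparams,
        "vocabulary": {t: int(i) for t, i in model._vectorizer.vocabulary_.items()},
        "coef": clf.coef_.tolist(),
        "intercept": clf.intercept_.tolist(),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> DiagnosisModel:
    """Load a model saved by :func:`save_model`; predictions round-trip exactly."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {payload.get('schema_version')}")
    tokenizer = TokenizerSpec(
        name=payload["tokenizer"]["name"],
        parameters=payload["tokenizer"]["parameters"],
    )
    hp = payload["hyperparams"]
    vectorizer = CountVectorizer(
        tokenizer=_make_tokenizer_callable(tokenizer),
        token_pattern=None,
        lowercase=False,
        binary=bool(hp.get("binary_counts", False)),
        vocabulary={t: int(i) for t, i in payload["vocabulary"].items()},
    )
    # instantiate the vocabulary-fixed vectorizer without refitting
    vectorizer._validate_vocabulary()
    clf = LogisticRegression(C=float(hp.get("C", 1.0)),
                             max_iter=int(hp.get("max_iter", 1000)))
    clf.classes_ = np.array(payload["label_set"], dtype=object)
    clf.coef_ = np.array(payload["coef"], dtype=float)
    clf.intercept_ = np.array(payload["intercept"], dtype=float)
    return DiagnosisModel(
        label_set=tuple(payload["label_set"]),
        vectorizer=vectorizer,
        classifier=clf,
        tokenizer=tokenizer,
        hyperparams=hp,
    )
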