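"""Consultation corpora: data model, I/O, tokenization, and fold construction.

A consultation record holds a patient's *initial description* (the free-text
self-report that opens an online consultation), the subsequent doctor-patient
*conversation*, and the disease label the doctor ultimately assigned.  The
union of initial description and conversation is the "complete information"
used to train the diagnosis classifier; the initial description alone is what
the deployed system sees.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConsultationRecord",
    "Corpus",
    "TokenizerSpec",
    "FoldAssignment",
    "CorpusFormatError",
    "UnknownTokenizerError",
    "register_tokenizer",
    "get_tokenizer",
    "tokenize",
    "read_corpus",
    "write_corpus",
    "complete_info",
    "filter_rare_classes",
    "stratified_folds",
    "fold_split",
]


class CorpusFormatError(ValueError):
    """A corpus file violates the expected structure (missing field, empty file)."""


class UnknownTokenizerError(ValueError):
    """A tokenizer spec names a scheme that is not registered."""


@dataclass(frozen=True)
class ConsultationRecord:
    """One patient consultation.

    Parameters
    ----------
    record_id:
        Opaque identifier; auto-assigned by file position when absent.
    initial_description:
        The patient's opening self-description. Must be non-blank.
    conversation:
        The follow-up doctor-patient conversation; may be empty.
    disease:
        The diagnosed disease label.
    """

    record_id: str
    initial_description: str
    conversation: str
    disease: str

    def __post_init__(self) -> None:
        if not self.initial_description.strip():
            raise ValueError(
                f"record {self.record_id!r}: initial_description is blank"
            )
        if not self.disease:
            raise ValueError(f"record {self.record_id!r}: disease label is empty")


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of consultation records.

    ``label_set`` is always the lexicographically sorted set of diseases that
    occur in ``records`` — it is derived, never supplied — so probability
    vectors indexed by it are reproducible across runs.
    """

    records: tuple[ConsultationRecord, ...]
    label_set: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = tuple(sorted({r.disease for r in self.records}))
        if len(labels) < 2:
            raise ValueError(
                f"a corpus needs at least 2 disease classes, got {len(labels)}"
            )
        object.__setattr__(self, "label_set", labels)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.label_set)

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.disease for r in self.records))

    def subset(self, indices: Iterable[int]) -> "Corpus":
        recs = tuple(self.records[i] for i in indices)
        return Corpus(records=recs)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenizerSpec:
    """Names a registered tokenization scheme plus scheme-specific options.

    Tokenization must be pure: the same text always yields the same tokens.
    The default ``whitespace`` scheme lowercases and splits on Unicode
    whitespace/punctuation boundaries, which is adequate for the synthetic
    vocabulary and for English text; CJK-aware segmenters can be plugged in
    through :func:`register_tokenizer`.
    """

    name: str = "whitespace"
    parameters: Mapping[str, object] = field(default_factory=dict)


_WORD_RE = re.compile(r"\w+", re.UNICODE)


def _whitespace_factory(params: Mapping[str, object]) -> Callable[[str], list[str]]:
    def tok(text: str) -> list[str]:
        return _WORD_RE.findall(text.lower())

    return tok


_TOKENIZERS: dict[str, Callable[[Mapping[str, object]], Callable[[str], list[str]]]] = {
    "whitespace": _whitespace_factory,
}


def register_tokenizer(
    name: str,
    factory: Callable[[Mapping[str, object]], Callable[[str], list[str]]],
) -> None:
    """Register a tokenizer scheme; ``factory(params)`` must return a pure callable."""
    _TOKENIZERS[name] = factory


def get_tokenizer(spec: TokenizerSpec) -> Callable[[str], list[str]]:
    try:
        factory = _TOKENIZERS[spec.name]
    except KeyError:
        raise UnknownTokenizerError(
            f"unknown tokenizer scheme {spec.name!r}; "
            f"registered: {sorted(_TOKENIZERS)}"
        ) from None
    return factory(spec.parameters)


def tokenize(text: str, spec: TokenizerSpec | None = None) -> list[str]:
    """Tokenize ``text`` under ``spec`` (default: whitespace scheme)."""
    return get_tokenizer(spec or TokenizerSpec())(text)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("initial_description", "conversation", "disease")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson"}:
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise CorpusFormatError(f"cannot infer corpus format from suffix {suffix!r}")


def _record_from_row(row: Mapping[str, object], position: int) -> ConsultationRecord:
    for key in _REQUIRED_FIELDS:
        if key not in row or row[key] is None:
            raise CorpusFormatError(f"row {position}: missing required field {key!r}")
    record_id = str(row.get("record_id") or f"r{position}")
    return ConsultationRecord(
        record_id=record_id,
        initial_description=str(row["initial_description"]),
        conversation=str(row["conversation"]),
        disease=str(row["disease"]),
    )


def read_corpus(path: str | Path, fmt: str | None = None) -> Corpus:
    """Read a corpus from a JSONL or CSV file.

    Rows are kept in file order; ``record_id`` defaults to ``r<position>``
    (1-based).  A missing required field raises :class:`CorpusFormatError`
    naming the offending row.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records: list[ConsultationRecord] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"row {i}: invalid JSON ({exc})") from exc
                records.append(_record_from_row(obj, i))
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=1):
                records.append(_record_from_row(row, i))
    else:
        raise CorpusFormatError(f"unsupported corpus format {fmt!r}")
    if not records:
        raise CorpusFormatError(f"{path}: empty corpus file")
    return Corpus(records=tuple(records))


def write_corpus(corpus: Corpus, path: str | Path, fmt: str | None = None) -> None:
    """Write a corpus as JSONL or CSV (UTF-8); inverse of :func:`read_corpus`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    rows = [
        {
            "record_id": r.record_id,
            "initial_description": r.initial_description,
            "conversation": r.conversation,
            "disease": r.disease,
        }
        for r in corpus.records
    ]
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["record_id", *_REQUIRED_FIELDS], quoting=csv.QUOTE_ALL
            )
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise CorpusFormatError(f"unsupported corpus format {fmt!r}")


# ---------------------------------------------------------------------------
# Derived text and class filtering
# ---------------------------------------------------------------------------

def complete_info(record: ConsultationRecord) -> str:
    """Concatenate initial description and conversation into one text.

    This is the "complete information" the diagnosis classifier is trained
    on.  An empty conversation returns the initial description unchanged.
    """
    if not record.conversation.strip():
        return record.initial_description
    return f"{record.initial_description} {record.conversation}"


def filter_rare_classes(corpus: Corpus, min_count: int) -> Corpus:
    """Drop records of diseases occurring fewer than ``min_count`` times.

    Stratified k-fold splitting requires every class to have at least k
    members, so experiments filter with ``min_count = n_folds`` first.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if min_count == 1:
        return corpus
    counts = corpus.class_counts()
    keep = {d for d, c in counts.items() if c >= min_count}
    if len(keep) < 2:
        raise ValueError(
            f"filtering at min_count={min_count} leaves {len(keep)} class(es); "
            "at least 2 are required"
        )
    recs = tuple(r for r in corpus.records if r.disease in keep)
    return Corpus(records=recs)


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Per-record fold indices for k-fold cross-validation."""

    n_folds: int
    assignments: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        bad = [a for a in self.assignments if not (0 <= a < self.n_folds)]
        if bad:
            raise ValueError(f"fold indices out of range: {bad[:5]}")

    def test_indices(self, fold: int) -> list[int]:
        return [i for i, a in enumerate(self.assignments) if a == fold]

    def train_indices(self, fold: int) -> list[int]:
        return [i for i, a in enumerate(self.assignments) if a != fold]


def stratified_folds(corpus: Corpus, n_folds: int, seed: int) -> FoldAssignment:
    """Assign each record to one of ``n_folds`` folds, stratified by disease.

    Per-class per-fold counts differ by at most 1.  Deterministic given
    ``seed``.  A class with fewer than ``n_folds`` records is an error
    (apply :func:`filter_rare_classes` first).
    """
    counts = corpus.class_counts()
    too_small = sorted(d for d, c in counts.items() if c < n_folds)
    if too_small:
        raise ValueError(
            f"classes with fewer than {n_folds} records cannot be stratified: "
            f"{too_small}"
        )
    y = [r.disease for r in corpus.records]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(corpus), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(corpus)), y)):
        assignments[test_idx] = fold
    return FoldAssignment(n_folds=n_folds, assignments=tuple(int(a) for a in assignments))


def fold_split(corpus: Corpus, folds: FoldAssignment, fold: int) -> tuple[Corpus, Corpus]:
    """Return the (train, test) corpora for one fold."""
    if not 0 <= fold < folds.n_folds:
        raise ValueError(f"fold {fold} out of range [0, {folds.n_folds})")
    return corpus.subset(folds.train_indices(fold)), corpus.subset(folds.test_indices(fold))
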