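"""Synthetic consultation corpora with a known prompting ground truth.

The generator emulates the statistical structure the prompting framework
assumes: each disease has a set of discriminative *signature* terms; the
patient's initial description reveals each signature term only with a small
probability and is padded with uninformative background vocabulary; the
withheld signature terms surface later in the doctor-patient conversation.
Class frequencies follow a power law over class rank, mirroring the heavy
skew of real consultation corpora.

Because the signature of every disease is known by construction,
:func:`oracle_best_prompts` gives an exact ground truth for which prompt
terms help diagnosis — the basis for end-to-end tests of the elicitation
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus import ConsultationRecord, Corpus

__all__ = ["GeneratorConfig", "GeneratorConfigError", "generate_corpus",
           "signature_terms", "oracle_best_prompts"]


class GeneratorConfigError(ValueError):
    """Raised with the full list of configuration violations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic consultation generator.

    Defaults describe the standard study conditions used throughout the test
    suite: 5 diseases, 500 consultations, 4 signature terms per disease of
    which ~30% are revealed up front, ~90% of withheld terms surfacing in the
    conversation, 8 background tokens of padding, and 1/rank class skew.

    Attributes
    ----------
    m:
        Number of diseases (>= 2).
    n:
        Number of consultation records (>= m).
    signature_size:
        Discriminative terms per disease; signatures are pairwise disjoint.
    background_size:
        Size of the shared, uninformative background vocabulary.
    reveal_prob:
        Probability that a signature term appears in the initial description.
    conversation_prob:
        Probability that a *withheld* signature term appears in the
        conversation instead.
    background_len:
        Background tokens padded onto each initial description.
    class_skew:
        Exponent of the power-law class-frequency distribution;
        P(class of rank r) proportional to r**(-class_skew).
    shared_terms:
        Optional number of extra terms shared between adjacent disease pairs,
        emulating symptoms common to several diseases.  These are emitted
        like signature terms but are never part of the oracle signature.
    seed:
        Seed for all randomness; generation is deterministic given it.
    """

    m: int = 5
    n: int = 500
    signature_size: int = 4
    background_size: int = 50
    reveal_prob: float = 0.3
    conversation_prob: float = 0.9
    background_len: int = 8
    class_skew: float = 1.0
    shared_terms: int = 0
    seed: int = 0

    def violations(self) -> list[str]:
        out = []
        if self.m < 2:
            out.append(f"m must be >= 2, got {self.m}")
        if self.n < self.m:
            out.append(f"n must be >= m, got n={self.n}, m={self.m}")
        if self.signature_size < 1:
            out.append(f"signature_size must be >= 1, got {self.signature_size}")
        if self.background_size < 1:
            out.append(f"background_size must be >= 1, got {self.background_size}")
        for name in ("reveal_prob", "conversation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                out.append(f"{name} must lie in [0, 1], got {v}")
        if self.background_len < 0:
            out.append(f"background_len must be >= 0, got {self.background_len}")
        if self.class_skew < 0:
            out.append(f"class_skew must be >= 0, got {self.class_skew}")
        if self.shared_terms < 0:
            out.append(f"shared_terms must be >= 0, got {self.shared_terms}")
        return out

    def validate(self) -> None:
        violations = self.violations()
        if violations:
            raise GeneratorConfigError("; ".join(violations))


def _labels(config: GeneratorConfig) -> list[str]:
    width = len(str(config.m - 1))
    return [f"disease_{j:0{width}d}" for j in range(config.m)]


def signature_terms(config: GeneratorConfig) -> dict[str, tuple[str, ...]]:
    """Map each disease label to its (disjoint) signature term tuple."""
    return {
        label: tuple(f"d{j}_sig{t}" for t in range(config.signature_size))
        for j, label in enumerate(_labels(config))
    }


def oracle_best_prompts(config: GeneratorConfig, disease: str) -> frozenset[str]:
    """Ground-truth best prompt terms for ``disease``: its signature set.

    By construction these are exactly the terms whose mention separates the
    disease from all others, so an ideal elicitation function ranks them top.
    """
    sigs = signature_terms(config)
    if disease not in sigs:
        raise ValueError(f"unknown disease {disease!r}; known: {sorted(sigs)}")
    return frozenset(sigs[disease])


def _shared_pool(config: GeneratorConfig) -> dict[int, list[str]]:
    """Per-class list of shared (cross-disease) terms, adjacent classes overlap."""
    pool: dict[int, list[str]] = {j: [] for j in range(config.m)}
    for j in range(config.m):
        nxt = (j + 1) % config.m
        for t in range(config.shared_terms):
            term = f"sh{j}_{t}"
            pool[j].append(term)
            pool[nxt].append(term)
    return pool


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a synthetic consultation corpus under ``config``.

    For each record: the disease is drawn from the skewed class distribution;
    each signature term enters the initial description with ``reveal_prob``,
    otherwise it enters the conversation with ``conversation_prob``;
    ``background_len`` uniform background tokens pad the initial description.
    Token order within each field is shuffled.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _labels(config)
    sigs = signature_terms(config)
    shared = _shared_pool(config)
    background = [f"bg_{i:03d}" for i in range(config.background_size)]

    ranks = np.arange(1, config.m + 1, dtype=float)
    weights = ranks ** (-config.class_skew)
    probs = weights / weights.sum()

    classes = rng.choice(config.m, size=config.n, p=probs)
    records = []
    for i in range(config.n):
        j = int(classes[i])
        label = labels[j]
        id_tokens: list[str] = []
        conv_tokens: list[str] = []
        for term in sigs[label]:
            if rng.random() < config.reveal_prob:
                id_tokens.append(term)
            elif rng.random() < config.conversation_prob:
                conv_tokens.append(term)
        for term in shared[j]:
            if rng.random() < config.reveal_prob:
                id_tokens.append(term)
            elif rng.random() < config.conversation_prob:
                conv_tokens.append(term)
        if config.background_len:
            id_tokens.extend(rng.choice(background, size=config.background_len))
        if not id_tokens:  # descriptions must be non-blank
            id_tokens.append(str(rng.choice(background)))
        rng.shuffle(id_tokens)
        rng.shuffle(conv_tokens)
        records.append(
            ConsultationRecord(
                record_id=f"syn{i}",
                initial_description=" ".join(id_tokens),
                conversation=" ".join(conv_tokens),
                disease=label,
            )
        )
    return Corpus(records=tuple(records))


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different seed (convenience for seed sweeps)."""
    return replace(config, seed=seed)
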