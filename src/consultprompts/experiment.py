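"""Cross-validated strategy sweep: the full evaluation protocol.

For each of k stratified folds, everything learned — the diagnosis model f,
the uncertainty threshold tau, the prompt vocabulary, and the elicitation
model g — is fitted on the training fold only, then every test-fold record
is pushed through the consult workflow for each (strategy, q) cell of the
grid.  Results are reported per fold and as fold-averaged aggregates.

Per-fold refitting of the vocabulary and g is deliberate: it is the only
reading of the protocol with no information flow from any test fold into a
trained artifact (see :func:`fit_fold_artifacts`, which consumes the
training corpus alone).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import (
    Corpus,
    FoldAssignment,
    TokenizerSpec,
    filter_rare_classes,
    fold_split,
    read_corpus,
    stratified_folds,
)
from .diagnosis import DiagnosisModel, fit_diagnosis
from .metrics import EvaluationReport, evaluate
from .prompts import (
    STRATEGIES,
    ElicitationModel,
    PromptVocabulary,
    apply_prompts,
    build_elicitation_labels,
    build_prompt_vocabulary,
    fit_elicitation,
    score_certainty,
    score_uncertainty,
)
from .uncertainty import UncertaintyConfig, calibrate_threshold, is_uncertain

__all__ = [
    "ExperimentConfig",
    "FoldArtifacts",
    "SweepResult",
    "fit_fold_artifacts",
    "run_experiment",
    "summarize",
]

logger = logging.getLogger(__name__)

_METRIC_COLUMNS = ("accuracy", "macro_f", "macro_auc", "macro_mcc", "averaged_entropy")


@dataclass(frozen=True)
class ExperimentConfig:
    """The experimental grid and all fitting options.

    ``min_count`` defaults to ``n_folds`` so every retained class can be
    stratified.  ``gate='always'`` applies prompts to every test document
    (the evaluation protocol); ``gate='threshold'`` prompts only documents
    whose prediction is more uncertain than the calibrated tau (the
    deployment workflow).
    """

    corpus_path: str | None = None
    n_folds: int = 5
    k: int = 100
    q_values: tuple[int, ...] = tuple(range(1, 11))
    strategies: tuple[str, ...] = STRATEGIES
    gate: str = "always"
    backend: str = "bow_logreg"
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    tokenizer: TokenizerSpec = field(default_factory=TokenizerSpec)
    seed: int = 0
    min_count: int | None = None
    hyperparams: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(f"unknown strategies {unknown}; valid: {STRATEGIES}")
        bad_q = [q for q in self.q_values if not 1 <= q <= self.k]
        if bad_q:
            raise ValueError(f"q values {bad_q} outside [1, k={self.k}]")
        if self.gate not in ("always", "threshold"):
            raise ValueError(f"gate must be 'always' or 'threshold', got {self.gate!r}")


@dataclass(frozen=True)
class FoldArtifacts:
    """Everything fitted from one training fold."""

    model: DiagnosisModel
    uncertainty: UncertaintyConfig
    vocabulary: PromptVocabulary
    elicitation: ElicitationModel | None


@dataclass(frozen=True)
class SweepResult:
    """Per-(strategy, q, fold) reports plus fold-averaged aggregates."""

    rows: dict[tuple[str, int, int], EvaluationReport]
    aggregate: dict[tuple[str, int], EvaluationReport]
    label_set: tuple[str, ...]
    folds: FoldAssignment


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def fit_fold_artifacts(
    train_corpus: Corpus,
    config: ExperimentConfig,
    fold_seed: int,
) -> FoldArtifacts:
    """Fit f, tau, the prompt vocabulary, and (if requested) g on one training fold.

    Consumes the training corpus only — by construction no test-fold text
    can influence any returned artifact.
    """
    model = fit_diagnosis(
        train_corpus,
        backend=config.backend,
        tokenizer=config.tokenizer,
        hyperparams=config.hyperparams,
        seed=fold_seed,
    )
    train_ids = [r.initial_description for r in train_corpus.records]
    ucfg = calibrate_threshold(model, train_ids, config.uncertainty)
    vocab = build_prompt_vocabulary(train_corpus, k=config.k, tokenizer=config.tokenizer)
    g = None
    if "learned" in config.strategies:
        labels = build_elicitation_labels(model, train_corpus, vocab)
        g = fit_elicitation(
            train_ids, labels, vocab,
            hyperparams=config.hyperparams, seed=fold_seed,
            tokenizer=config.tokenizer,
        )
    return FoldArtifacts(model=model, uncertainty=ucfg, vocabulary=vocab, elicitation=g)


def _strategy_scores(
    artifacts: FoldArtifacts, strategy: str, test_ids: Sequence[str]
) -> np.ndarray:
    """(n_test, k) per-term scores for one strategy; higher = prompt sooner."""
    vocab = artifacts.vocabulary
    if strategy == "learned":
        assert artifacts.elicitation is not None
        return artifacts.elicitation.score_batch(list(test_ids))
    scorer = score_certainty if strategy == "certainty" else score_uncertainty
    out = np.empty((len(test_ids), vocab.k))
    for i, x in enumerate(test_ids):
        out[i] = scorer(artifacts.model, x, vocab, artifacts.uncertainty).scores
    return out


def _evaluate_fold(
    artifacts: FoldArtifacts,
    test_corpus: Corpus,
    config: ExperimentConfig,
    label_set: Sequence[str],
) -> dict[tuple[str, int], EvaluationReport]:
    test_ids = [r.initial_description for r in test_corpus.records]
    true = [r.disease for r in test_corpus.records]
    base_proba = artifacts.model.predict_proba_batch(test_ids)
    if config.gate == "threshold":
        gated = np.array(
            [is_uncertain(row, artifacts.uncertainty) for row in base_proba]
        )
    else:
        gated = np.ones(len(test_ids), dtype=bool)

    out: dict[tuple[str, int], EvaluationReport] = {}
    for strategy in config.strategies:
        if strategy == "none":
            report = evaluate(true, base_proba, label_set)
            for q in config.q_values:
                out[(strategy, q)] = report
            continue
        scores = _strategy_scores(artifacts, strategy, test_ids)
        order = np.argsort(-scores, axis=1, kind="stable")
        terms = artifacts.vocabulary.terms
        for q in config.q_values:
            q_eff = min(q, len(terms))
            proba = base_proba.copy()
            prompted_idx = [i for i in range(len(test_ids)) if gated[i]]
            if prompted_idx:
                texts = [
                    apply_prompts(
                        test_ids[i], [terms[j] for j in order[i, :q_eff]]
                    )
                    for i in prompted_idx
                ]
                proba[prompted_idx] = artifacts.model.predict_proba_batch(texts)
            out[(strategy, q)] = evaluate(true, proba, label_set)
    return out


def _mean_report(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    return EvaluationReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        macro_f=float(np.mean([r.macro_f for r in reports])),
        macro_auc=float(np.mean([r.macro_auc for r in reports])),
        macro_mcc=float(np.mean([r.macro_mcc for r in reports])),
        averaged_entropy=float(np.mean([r.averaged_entropy for r in reports])),
        n_evaluated=int(sum(r.n_evaluated for r in reports)),
    )


def run_experiment(config: ExperimentConfig, corpus: Corpus | None = None) -> SweepResult:
    """Run the full cross-validated strategy sweep.

    ``corpus`` may be passed directly; otherwise ``config.corpus_path`` is
    read.  Rare classes (fewer records than ``n_folds``) are filtered first.
    Fully deterministic given ``config.seed``.
    """
    if corpus is None:
        if config.corpus_path is None:
            raise ValueError("either a corpus or config.corpus_path is required")
        corpus = read_corpus(config.corpus_path)
    min_count = config.min_count if config.min_count is not None else config.n_folds
    filtered = filter_rare_classes(corpus, min_count)
    if len(filtered) != len(corpus):
        logger.info(
            "filtered %d records of rare classes (min_count=%d)",
            len(corpus) - len(filtered), min_count,
        )
    seeds = _derived_seeds(config.seed, config.n_folds + 1)
    folds = stratified_folds(filtered, config.n_folds, seeds[-1])
    rows: dict[tuple[str, int, int], EvaluationReport] = {}
    for fold in range(config.n_folds):
        train_corpus, test_corpus = fold_split(filtered, folds, fold)
        artifacts = fit_fold_artifacts(train_corpus, config, seeds[fold])
        logger.info(
            "fold %d: %d train / %d test records, vocabulary of %d terms",
            fold, len(train_corpus), len(test_corpus), artifacts.vocabulary.k,
        )
        fold_reports = _evaluate_fold(artifacts, test_corpus, config, filtered.label_set)
        for (strategy, q), report in fold_reports.items():
            rows[(strategy, q, fold)] = report
    aggregate = {
        (strategy, q): _mean_report(
            [rows[(strategy, q, fold)] for fold in range(config.n_folds)]
        )
        for strategy in config.strategies
        for q in config.q_values
    }
    return SweepResult(
        rows=rows, aggregate=aggregate, label_set=filtered.label_set, folds=folds
    )


def summarize(
    result: SweepResult,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate a sweep as (per-fold rows, fold-averaged aggregate) frames.

    When ``out_dir`` is given, writes ``rows.csv`` and ``aggregate.csv``
    (12 significant digits) and, with ``plots=True``, one metric-vs-q panel
    per metric under ``plots/``.
    """
    row_records = [
        {"strategy": s, "q": q, "fold": fold, **report.scalars(),
         "n_evaluated": report.n_evaluated}
        for (s, q, fold), report in sorted(result.rows.items())
    ]
    agg_records = [
        {"strategy": s, "q": q, **report.scalars(),
         "n_evaluated": report.n_evaluated}
        for (s, q), report in sorted(result.aggregate.items())
    ]
    rows_df = pd.DataFrame(row_records)
    agg_df = pd.DataFrame(agg_records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows_df.to_csv(out / "rows.csv", index=False, float_format="%.12g")
        agg_df.to_csv(out / "aggregate.csv", index=False, float_format="%.12g")
        if plots:
            _plot_panels(agg_df, out / "plots")
    return rows_df, agg_df


def _plot_panels(agg_df: pd.DataFrame, plot_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    for metric in _METRIC_COLUMNS:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for strategy, group in agg_df.groupby("strategy"):
            group = group.sort_values("q")
            ax.plot(group["q"], group[metric], marker="o", label=strategy)
        ax.set_xlabel("number of prompts q")
        ax.set_ylabel(metric)
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_dir / f"{metric}.png", dpi=120)
        plt.close(fig)
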