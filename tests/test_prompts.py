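"""Prompt vocabulary, elicitation strategies, selection, and consult."""

import inspect
import math

import numpy as np
import pytest

from consultprompts.corpus import ConsultationRecord, Corpus
from consultprompts.diagnosis import fit_diagnosis
from consultprompts.prompts import (
    PromptScores,
    PromptVocabulary,
    apply_prompts,
    build_elicitation_labels,
    build_prompt_vocabulary,
    consult,
    fit_elicitation,
    load_elicitation,
    save_elicitation,
    score_certainty,
    score_learned,
    score_uncertainty,
    select_prompts,
)
from consultprompts.synthetic import (
    GeneratorConfig,
    generate_corpus,
    oracle_best_prompts,
)
from consultprompts.corpus import tokenize
from consultprompts.uncertainty import UncertaintyConfig, entropy


def _corpus_with_conversations(convs, diseases=None):
    diseases = diseases or ["A", "B"] * ((len(convs) + 1) // 2)
    return Corpus(records=tuple(
        ConsultationRecord(f"r{i}", "x", conv, diseases[i])
        for i, conv in enumerate(convs)
    ))


class TestVocabulary:
    def test_toy_tfidf_excludes_the_ubiquitous_term(self):
        """Hand oracle on ["a a b", "a c"]: weight(t) = tf x ln((1+N)/(1+df)).

        a: 3 x ln(3/3) = 0; b: 1 x ln(3/2); c: 1 x ln(3/2).  Top-2 is then
        (b, c) by the lexicographic tie-break, excluding "a".
        """
        corpus = _corpus_with_conversations(["a a b", "a c"])
        vocab = build_prompt_vocabulary(corpus, k=2)
        assert vocab.terms == ("b", "c")
        assert vocab.tfidf_weights == pytest.approx(
            [math.log(3 / 2), math.log(3 / 2)]
        )

    def test_k_beyond_distinct_terms_warns_and_returns_all(self):
        corpus = _corpus_with_conversations(["a b", "c"])
        with pytest.warns(UserWarning, match="distinct conversation terms"):
            vocab = build_prompt_vocabulary(corpus, k=50)
        assert set(vocab.terms) == {"a", "b", "c"}

    def test_default_vocabulary_size_is_100(self):
        sig = inspect.signature(build_prompt_vocabulary)
        assert sig.parameters["k"].default == 100

    def test_order_is_weight_descending_then_lexicographic(self):
        corpus = _corpus_with_conversations(["b b", "d", "c", "a a"])
        vocab = build_prompt_vocabulary(corpus, k=4)
        assert vocab.terms == ("a", "b", "c", "d")


class TestElicitationLabels:
    def test_helpful_term_gets_label_one_and_oov_term_zero(self, separable_corpus):
        model = fit_diagnosis(separable_corpus, seed=0)
        vocab = PromptVocabulary(terms=("cough", "zzz_oov"), tfidf_weights=np.ones(2))
        # records alternate flu ("fever cough") / measles ("rash itch")
        labels = build_elicitation_labels(model, separable_corpus, vocab)
        flu_rows = [i for i, r in enumerate(separable_corpus.records)
                    if r.disease == "flu"]
        measles_rows = [i for i, r in enumerate(separable_corpus.records)
                        if r.disease == "measles"]
        assert all(labels.matrix[i, 0] == 1 for i in flu_rows)  # cough helps flu
        assert all(labels.matrix[i, 0] == 0 for i in measles_rows)
        assert (labels.matrix[:, 1] == 0).all()  # OOV term changes nothing


class TestFitElicitation:
    def test_degenerate_labels_yield_constant_scorers(self):
        from consultprompts.prompts import ElicitationLabels

        vocab = PromptVocabulary(terms=("t0", "t1"), tfidf_weights=np.ones(2))
        labels = ElicitationLabels(matrix=np.array([[1, 0]] * 6))
        g = fit_elicitation([f"doc {i}" for i in range(6)], labels, vocab)
        scores = g.score("anything").scores
        assert scores[0] == 1.0 and scores[1] == 0.0

    def test_dimension_mismatch_is_an_error(self):
        from consultprompts.prompts import ElicitationLabels

        vocab = PromptVocabulary(terms=("t0",), tfidf_weights=np.ones(1))
        labels = ElicitationLabels(matrix=np.zeros((3, 1), dtype=int))
        with pytest.raises(ValueError, match="does not match"):
            fit_elicitation(["a", "b"], labels, vocab)

    def test_learned_scorer_recovers_the_signal_term(self):
        """When each class has one signature term that is usually revealed,
        g ranks that term top-1 for >=80% of held-out class members."""
        hits = total = 0
        for seed in range(3):
            cfg = GeneratorConfig(
                m=5, n=500, signature_size=1, background_size=20,
                reveal_prob=0.9, conversation_prob=1.0, background_len=5,
                class_skew=0.0, seed=seed,
            )
            corpus = generate_corpus(cfg)
            train, test = corpus.subset(range(400)), corpus.subset(range(400, 500))
            model = fit_diagnosis(train, seed=seed)
            vocab = build_prompt_vocabulary(train, k=5)
            labels = build_elicitation_labels(model, train, vocab)
            g = fit_elicitation(
                [r.initial_description for r in train.records], labels, vocab,
                seed=seed,
            )
            for r in test.records:
                (oracle_term,) = oracle_best_prompts(cfg, r.disease)
                scores = score_learned(g, r.initial_description)
                top = select_prompts(scores, vocab, q=1)[0]
                hits += top == oracle_term
                total += 1
        assert hits / total >= 0.8

    def test_persistence_round_trips_scores_exactly(self, tmp_path):
        from consultprompts.prompts import ElicitationLabels

        rng = np.random.default_rng(0)
        vocab = PromptVocabulary(terms=("t0", "t1", "t2"), tfidf_weights=np.ones(3))
        docs = [f"w{rng.integers(5)} w{rng.integers(5)}" for _ in range(20)]
        labels = ElicitationLabels(matrix=rng.integers(0, 2, size=(20, 3)))
        g = fit_elicitation(docs, labels, vocab, seed=1)
        save_elicitation(g, tmp_path / "g.json")
        back = load_elicitation(tmp_path / "g.json")
        for probe in ["w0 w3", "", "w4"]:
            assert np.array_equal(back.score(probe).scores, g.score(probe).scores)


class TestStrategyScores:
    @pytest.fixture(scope="class")
    def fitted(self, small_corpus):
        model = fit_diagnosis(small_corpus, seed=0)
        vocab = build_prompt_vocabulary(small_corpus, k=10)
        return model, vocab

    def test_certainty_matches_brute_force_entropy(self, fitted):
        model, vocab = fitted
        x = "bg_001 d1_sig0"
        scores = score_certainty(model, x, vocab)
        brute = np.array([
            -entropy(model.predict_proba(f"{x} {t}")) for t in vocab.terms
        ])
        assert scores.scores == pytest.approx(brute, abs=1e-12)

    def test_uncertainty_is_the_exact_negation(self, fitted):
        model, vocab = fitted
        for x in ["bg_001", "d2_sig0 d2_sig1", ""]:
            c = score_certainty(model, x, vocab).scores
            u = score_uncertainty(model, x, vocab).scores
            assert np.array_equal(u, -c)

    def test_reversed_rankings_end_to_end(self, fitted):
        model, vocab = fitted
        x = "bg_002 d3_sig1"
        top_c = select_prompts(score_certainty(model, x, vocab), vocab, q=vocab.k)
        top_u = select_prompts(score_uncertainty(model, x, vocab), vocab, q=vocab.k)
        c_scores = score_certainty(model, x, vocab).scores
        if len(set(c_scores)) == vocab.k:  # strict reversal needs distinct scores
            assert top_c == top_u[::-1]


class TestSelection:
    def test_selects_highest_scores_in_order(self):
        vocab = PromptVocabulary(terms=("t1", "t2", "t3"), tfidf_weights=np.ones(3))
        scores = PromptScores(scores=np.array([0.9, 0.1, 0.5]))
        assert select_prompts(scores, vocab, q=2) == ["t1", "t3"]

    def test_q_equal_k_returns_all_terms(self):
        vocab = PromptVocabulary(terms=("a", "b"), tfidf_weights=np.ones(2))
        scores = PromptScores(scores=np.array([0.1, 0.9]))
        assert select_prompts(scores, vocab, q=2) == ["b", "a"]

    def test_q_beyond_k_is_an_error(self):
        vocab = PromptVocabulary(terms=("a",), tfidf_weights=np.ones(1))
        with pytest.raises(ValueError):
            select_prompts(PromptScores(scores=np.zeros(1)), vocab, q=2)

    def test_ties_break_by_vocabulary_order(self):
        vocab = PromptVocabulary(terms=("a", "b", "c"), tfidf_weights=np.ones(3))
        scores = PromptScores(scores=np.array([0.5, 0.5, 0.5]))
        assert select_prompts(scores, vocab, q=2) == ["a", "b"]


class TestApplyPrompts:
    def test_appends_with_single_spaces(self):
        assert apply_prompts("fever", ["cough", "rash"]) == "fever cough rash"

    def test_empty_terms_leave_text_unchanged(self):
        assert apply_prompts("fever", []) == "fever"

    def test_token_count_is_additive(self):
        x, terms = "fever chills", ["cough", "rash", "ache"]
        assert len(tokenize(apply_prompts(x, terms))) == len(tokenize(x)) + len(terms)


class TestConsult:
    @pytest.fixture(scope="class")
    def fitted(self, small_corpus):
        model = fit_diagnosis(small_corpus, seed=0)
        vocab = build_prompt_vocabulary(small_corpus, k=10)
        labels = build_elicitation_labels(model, small_corpus, vocab)
        g = fit_elicitation(
            [r.initial_description for r in small_corpus.records], labels, vocab
        )
        return model, vocab, g

    def test_none_strategy_equals_bare_prediction(self, fitted):
        model, _, _ = fitted
        for x in ["bg_001 d0_sig0", "bg_004"]:
            result = consult(model, "none", x)
            assert np.array_equal(
                result.distribution.probabilities,
                model.predict_proba(x).probabilities,
            )
            assert result.applied_terms == ()

    def test_huge_threshold_collapses_every_strategy_to_no_prompts(self, fitted):
        model, vocab, g = fitted
        cfg = UncertaintyConfig(threshold=1e9)
        for strategy in ("learned", "certainty", "uncertainty"):
            result = consult(
                model, strategy, "bg_001", config=cfg, gate="threshold",
                g=g, vocab=vocab,
            )
            assert result.applied_terms == ()
            assert np.array_equal(
                result.distribution.probabilities,
                model.predict_proba("bg_001").probabilities,
            )

    def test_learned_without_g_is_an_error(self, fitted):
        model, vocab, _ = fitted
        with pytest.raises(ValueError, match="elicitation model"):
            consult(model, "learned", "bg_001", vocab=vocab)

    def test_applied_terms_are_a_vocabulary_subset_of_length_q(self, fitted):
        model, vocab, g = fitted
        result = consult(model, "learned", "bg_001 d1_sig0", q=3, g=g)
        assert len(result.applied_terms) == 3
        assert set(result.applied_terms) <= set(vocab.terms)

    def test_oracle_signature_terms_fix_a_misclassified_record(
        self, small_corpus, small_generator_config, fitted
    ):
        """Appending a record's true signature flips at least one base error."""
        model, _, _ = fitted
        flipped = 0
        for r in small_corpus.records:
            if model.predict_label(r.initial_description) == r.disease:
                continue
            terms = sorted(oracle_best_prompts(small_generator_config, r.disease))
            if model.predict_label(apply_prompts(r.initial_description, terms)) == r.disease:
                flipped += 1
        assert flipped >= 1
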