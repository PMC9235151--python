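import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from consultprompts.corpus import ConsultationRecord, Corpus
from consultprompts.diagnosis import fit_diagnosis
from consultprompts.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def separable_corpus() -> Corpus:
    """Two perfectly separable classes, five records each."""
    records = []
    for i in range(5):
        records.append(ConsultationRecord(f"a{i}", "fever cough", "", "flu"))
        records.append(ConsultationRecord(f"b{i}", "rash itch", "", "measles"))
    return Corpus(records=tuple(records))


@pytest.fixture(scope="session")
def small_generator_config() -> GeneratorConfig:
    """A quick-to-fit synthetic corpus with clear but partial ID signal."""
    return GeneratorConfig(
        m=4, n=160, signature_size=3, background_size=20,
        reveal_prob=0.4, conversation_prob=0.9, background_len=5,
        class_skew=1.0, seed=3,
    )


@pytest.fixture(scope="session")
def small_corpus(small_generator_config) -> Corpus:
    return generate_corpus(small_generator_config)


@pytest.fixture(scope="session")
def small_model(small_corpus):
    return fit_diagnosis(small_corpus, seed=0)
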