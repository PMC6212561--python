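import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from temporient import (  # noqa: E402
    GeneratorConfig,
    filter_valid,
    generate_corpus,
    tag_lexicon,
)

WORKED_SENTENCE = "In 2019, I will have remembered this example"
WORKED_TAGS = ("IN", "CD", ",", "PRP", "MD", "VB", "VBN", "DT", "NN")


@pytest.fixture(scope="session")
def worked_sentence():
    """The shared worked-example sentence, tagged by the built-in tagger."""
    return tag_lexicon(WORKED_SENTENCE)


@pytest.fixture(scope="session")
def default_corpus():
    """A default-config synthetic corpus (2884 records, fixed seed)."""
    return generate_corpus(GeneratorConfig(seed=20180))


@pytest.fixture(scope="session")
def default_valid(default_corpus):
    kept, _ = filter_valid(default_corpus)
    return kept
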