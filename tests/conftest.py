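import pytest

from adrminer import synthgen

from util import make_lexicon


@pytest.fixture
def drug_lex():
    return make_lexicon(["ketotop", "antiphlamine"], "drug")


@pytest.fixture
def adr_lex():
    # ids chosen to mirror the tagged-token rendering convention
    from adrminer.lexicon import Lexicon, LexiconEntry

    return Lexicon(
        [
            LexiconEntry("blisters", 153, "adr"),
            LexiconEntry("itch", 156, "adr"),
            LexiconEntry("muscle pain", 10, "adr"),
            LexiconEntry("rash", 11, "adr"),
        ],
        "adr",
    )


@pytest.fixture
def stop_lex():
    return make_lexicon(["and", "the", "i", "a"], "stopword")


@pytest.fixture(scope="session")
def keto_bundle():
    """One ketoprofen-like synthetic bundle shared across read-only tests."""
    return synthgen.generate(synthgen.preset("ketoprofen-like", seed=11))
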