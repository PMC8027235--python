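import pytest

from thermotriage.corpus import TextUnit, normalize_text
from thermotriage.lexicon import build_default_lexicon
from thermotriage.textprep import default_stopwords, preprocess


@pytest.fixture(scope="session")
def lex():
    return build_default_lexicon()


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


def make_unit(text, index=0, kind="paragraph"):
    return TextUnit(kind, index, normalize_text(text))


@pytest.fixture
def unit_of():
    """Factory: raw text -> (TextUnit, TokenizedUnit)."""

    def _make(text):
        u = make_unit(text)
        return u, preprocess(u)

    return _make
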