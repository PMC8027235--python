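"""Token-level normalization: tokenization, stopword removal, lemmatization.

Concept-word matching runs on lowercase noun-mode lemmas; symbol and
unit-of-measure matching runs on the raw unit text, because lowercasing
and lemmatization destroy case-sensitive symbols such as the Delta-G
family and ``kcal/mol``. This module produces the lemma stream and keeps
a character span per token so every lemma can be mapped back to the raw
text for highlighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import FrozenSet, List, Optional, Tuple, Union

from .corpus import TextUnit

__all__ = [
    "TokenizedUnit",
    "preprocess",
    "lemmatize_noun",
    "default_stopwords",
    "load_stopwords",
]


@dataclass(frozen=True)
class TokenizedUnit:
    """Lowercase lemma stream of one unit, with raw-text spans per token."""

    unit: TextUnit
    tokens: Tuple[str, ...]
    raw_spans: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.raw_spans):
            raise ValueError("tokens and raw_spans must be parallel")


# Irregular noun plurals the suffix rules below cannot handle. Words that
# are their own lemma (data, species, series) are listed to stop the
# generic -s rule from mangling them.
_NOUN_EXCEPTIONS = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "geese": "goose",
    "mice": "mouse",
    "media": "medium",
    "data": "data",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "analyses": "analysis",
    "hypotheses": "hypothesis",
    "theses": "thesis",
    "axes": "axis",
    "bases": "base",
    "indices": "index",
    "matrices": "matrix",
    "vertices": "vertex",
    "helices": "helix",
    "species": "species",
    "series": "series",
}

# (suffix, replacement) detachment rules, tried in order; first match wins.
_NOUN_RULES = (
    ("sses", "ss"),
    ("ches", "ch"),
    ("shes", "sh"),
    ("xes", "x"),
    ("zes", "z"),
    ("ies", "y"),
)


def lemmatize_noun(word: str) -> str:
    """Noun-mode lemma of a lowercase word (suffix-rule morphology).

    Plural nouns are reduced to their singular ("proteins" -> "protein",
    "studies" -> "study"); -ing forms are untouched, so domain nouns like
    "unfolding" survive as-is. Words not ending in a plural suffix are
    returned unchanged.
    """
    if word in _NOUN_EXCEPTIONS:
        return _NOUN_EXCEPTIONS[word]
    for suffix, repl in _NOUN_RULES:
        if word.endswith(suffix) and len(word) > len(suffix) + 1:
            return word[: -len(suffix)] + repl
    if (
        len(word) > 3
        and word.endswith("s")
        and word[-2].isalnum()  # never leave trailing punctuation behind
        and not word.endswith(("ss", "us", "is"))
    ):
        return word[:-1]
    return word


@lru_cache(maxsize=1)
def default_stopwords() -> FrozenSet[str]:
    """The packaged frozen English stopword list."""
    text = resources.files("thermotriage").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_stopwords(path: Union[str, Path]) -> FrozenSet[str]:
    """Load a one-word-per-line stopword file (overrides the default)."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip()
        if w and not w.startswith("#"):
            words.add(w.lower())
    return frozenset(words)


def _word_spans(text: str) -> List[Tuple[int, int]]:
    """Spans of whitespace-delimited words, trimmed of edge punctuation."""
    spans = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        # trim punctuation from both ends, keep internal hyphens/slashes
        a, b = i, j
        while a < b and not text[a].isalnum():
            a += 1
        while b > a and not text[b - 1].isalnum():
            b -= 1
        if a < b:
            spans.append((a, b))
        i = j
    return spans


def preprocess(unit: TextUnit, stopwords: Optional[FrozenSet[str]] = None) -> TokenizedUnit:
    """Lowercase, drop stopwords, lemmatize; keep raw spans per token.

    Hyphenated words are kept whole (``two-state`` is one token) and
    punctuation-only words are dropped. The token stream is what the
    concept-word matcher consumes; spans map each token back to the raw
    unit text.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    tokens: List[str] = []
    spans: List[Tuple[int, int]] = []
    for a, b in _word_spans(unit.text):
        word = unit.text[a:b].lower()
        if word in stopwords:
            continue
        lemma = lemmatize_noun(word)
        if not lemma or lemma in stopwords:
            continue
        tokens.append(lemma)
        spans.append((a, b))
    return TokenizedUnit(unit=unit, tokens=tuple(tokens), raw_spans=tuple(spans))
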