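"""Synthetic labeled HTML corpora with controlled term injection.

Real optimization corpora for this problem are bulk full-text downloads
with curated labels; for development and testing this module generates
small stand-in corpora whose statistical structure is controlled:
positive articles carry thermodynamic concept words, variable symbols
and units of measure at high per-unit rates, negative articles carry
them at low rates plus computational-concept vocabulary. Filler text is
drawn from a fixed pseudo-word vocabulary (pronounceable random
strings), so no filler can accidentally match a lexicon pattern — an
assertion enforces that pure filler scores zero.

Generation is a pure function of (spec, seed): identical inputs yield
byte-identical corpora.

The defaults mirror the conditions used throughout the test suite: 50
positive and 50 negative articles, concept words planted at a 0.9
per-unit rate in positives versus 0.05 in negatives.
"""

from __future__ import annotations

import html as html_mod
import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Tuple, Union

from .corpus import Document, parse_article_html
from .lexicon import build_default_lexicon, match_unit
from .textprep import default_stopwords, preprocess

__all__ = [
    "CorpusSpec",
    "LabeledCorpus",
    "generate_corpus",
    "write_corpus",
    "worked_example_html",
    "worked_example_document",
]

TC_WORDS = ("unfolding", "two-state", "denaturant", "dichroism", "midpoint")
TV_TERMS = ("ΔΔG", "ΔG", "ΔTm", "ΔH", "ΔCp", "Tm", "Cp")
UM_TERMS = ("kcal/mol", "kJ/mol", "kcal/mol/K", "°C")
CC_TERMS = ("simulation", "molecular dynamics", "force field",
            "gromacs", "amber", "predict", "md simulation")

_CONSONANTS = "bcdfgjklnpqrstvwz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class CorpusSpec:
    """Size, injection rates and seed of a synthetic corpus.

    Rates are per-unit injection probabilities, separately for positive
    and negative articles.
    """

    n_pos: int = 50
    n_neg: int = 50
    units_per_doc: Tuple[int, int] = (4, 8)
    rate_tc_pos: float = 0.9
    rate_tc_neg: float = 0.05
    rate_tv_pos: float = 0.6
    rate_tv_neg: float = 0.05
    rate_um_pos: float = 0.6
    rate_um_neg: float = 0.05
    rate_cc_pos: float = 0.05
    rate_cc_neg: float = 0.3
    filler_vocab_size: int = 200
    filler_words_per_unit: Tuple[int, int] = (6, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("corpus sizes must be non-negative")
        for name, val in asdict(self).items():
            if name.startswith("rate_") and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")


@dataclass
class LabeledCorpus:
    """Generated articles as (doc_id, html, label) with label pos/neg."""

    documents: List[Tuple[str, str, str]] = field(default_factory=list)
    spec: CorpusSpec = field(default_factory=CorpusSpec)

    def parsed(self) -> List[Tuple[Document, str]]:
        return [
            (parse_article_html(html, doc_id=doc_id), label)
            for doc_id, html, label in self.documents
        ]


def _pseudo_word(rng: random.Random) -> str:
    n_syll = rng.randint(2, 4)
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
    )


def _make_filler_vocab(rng: random.Random, size: int) -> List[str]:
    """Pseudo-words guaranteed inert under the default lexicon."""
    lex = build_default_lexicon()
    stop = default_stopwords()
    vocab: List[str] = []
    while len(vocab) < size:
        w = _pseudo_word(rng)
        if w in stop or w in vocab:
            continue
        probe = parse_article_html(f"<p>{w}</p>").units[0]
        if match_unit(probe, preprocess(probe, stop), lex).matches:
            continue  # paranoia: CV syllables should never hit the lexicon
        vocab.append(w)
    return vocab


def _unit_words(rng: random.Random, spec: CorpusSpec, vocab: List[str],
                positive: bool) -> List[str]:
    lo, hi = spec.filler_words_per_unit
    words = [rng.choice(vocab) for _ in range(rng.randint(lo, hi))]
    pick = lambda rate, terms: rng.random() < rate and words.insert(
        rng.randint(0, len(words)), rng.choice(terms)
    )
    if positive:
        pick(spec.rate_tc_pos, TC_WORDS)
        pick(spec.rate_tv_pos, TV_TERMS)
        pick(spec.rate_um_pos, UM_TERMS)
        pick(spec.rate_cc_pos, CC_TERMS)
    else:
        pick(spec.rate_tc_neg, TC_WORDS)
        pick(spec.rate_tv_neg, TV_TERMS)
        pick(spec.rate_um_neg, UM_TERMS)
        pick(spec.rate_cc_neg, CC_TERMS)
    return words


def _document_html(rng: random.Random, spec: CorpusSpec, vocab: List[str],
                   positive: bool) -> str:
    lo, hi = spec.units_per_doc
    n_units = rng.randint(lo, hi)
    parts = ["<html><body>"]
    for i in range(n_units):
        words = _unit_words(rng, spec, vocab, positive)
        text = html_mod.escape(" ".join(words), quote=False)
        if i == n_units - 1 and n_units > 1:
            # last unit rendered as a one-row table to exercise both kinds
            cells = "".join(f"<td>{html_mod.escape(w, quote=False)}</td>" for w in words)
            parts.append(f"<table><tr>{cells}</tr></table>")
        else:
            parts.append(f"<p>{text}</p>")
    parts.append("</body></html>")
    return "".join(parts)


def generate_corpus(spec: CorpusSpec) -> LabeledCorpus:
    """Generate the labeled corpus described by ``spec`` (deterministic)."""
    rng = random.Random(spec.seed)
    vocab = _make_filler_vocab(rng, spec.filler_vocab_size)
    docs: List[Tuple[str, str, str]] = []
    for i in range(spec.n_pos):
        docs.append((f"pos{i:04d}", _document_html(rng, spec, vocab, True), "pos"))
    for i in range(spec.n_neg):
        docs.append((f"neg{i:04d}", _document_html(rng, spec, vocab, False), "neg"))
    return LabeledCorpus(documents=docs, spec=spec)


def write_corpus(corpus: LabeledCorpus, outdir: Union[str, Path]) -> Path:
    """Write .html files, labels.tsv and the serialized spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = []
    for doc_id, html, label in corpus.documents:
        (outdir / f"{doc_id}.html").write_text(html, encoding="utf-8")
        labels.append((f"{doc_id}", label))
    with open(outdir / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\n")
        for doc_id, label in labels:
            fh.write(f"{doc_id}\t{label}\n")
    spec_dict = asdict(corpus.spec)
    (outdir / "spec.json").write_text(json.dumps(spec_dict, indent=2), encoding="utf-8")
    return outdir


# A fixed worked example with hand-checkable unit scores (6, 1, -2):
# paragraph 1 sums ΔΔG (+3) + unfolding (+1) + kcal/mol (+2); paragraph 2
# has only midpoint (+1); paragraph 3 is the composite md-simulation
# penalty (-2). Synthetic document, written for this package.
WORKED_EXAMPLE_HTML = (
    "<html><body>"
    "<p>The &#x394;&#x394;G of unfolding was 2.3 kcal/mol for the V31A variant.</p>"
    "<p>The midpoint temperature of the wild type was higher.</p>"
    "<p>Independent md simulation runs were also compared.</p>"
    "</body></html>"
)


def worked_example_html() -> str:
    return WORKED_EXAMPLE_HTML


def worked_example_document() -> Document:
    return parse_article_html(WORKED_EXAMPLE_HTML, doc_id="worked_example")
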