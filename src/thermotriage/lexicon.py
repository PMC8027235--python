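"""The scored term classes and the unit-level matcher.

Four classes of terms carry integer scores:

* **TC** — thermodynamic concepts (``unfolding``, ``two-state``,
  ``denaturant``, ``dichroism``, ``midpoint``), +1 each, matched on
  lemmas.
* **TV** — thermodynamic-variable symbols: bare ``Cp``/``Tm`` +1, a
  single-difference symbol (ΔG, ΔTm, ...) +2, a double difference
  (ΔΔG, ...) +3; matched on the raw text, with ASCII fallbacks
  (``dG``, ``ddG``, ``delta G``) for the Greek delta.
* **UM** — units of measure: ``°C`` +1, an energy-per-amount string
  such as ``kcal/mol`` or ``kJ/mol/K`` +2; matched on the raw text.
* **CC** — computational concepts (simulation, molecular dynamics,
  force field, charmm, gromacs, amber, PBSA, GBSA, predict), −1 each,
  and the composite ``md simulation`` at −2; matched on lowercased raw
  text at word boundaries.

Two further classes are annotation-only and never scored: **BIND**
(binding-process vocabulary) and **VARIANT** (amino-acid substitution
notation, e.g. ``V31A`` or ``Ala123Gly``).

Overlapping candidate matches are resolved longest-first, then
leftmost, so ``ΔΔG`` is one +3 match (not +3 and +2) and
``md simulation`` is one −2 match (not −2 and −1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .corpus import TextUnit
from .textprep import TokenizedUnit

__all__ = [
    "TermClass",
    "SCORED_CLASSES",
    "ALL_CLASSES",
    "LexiconEntry",
    "Lexicon",
    "Match",
    "MatchSet",
    "build_default_lexicon",
    "match_unit",
    "find_variants",
]


class TermClass(str, Enum):
    TC = "TC"  # thermodynamic concepts
    TV = "TV"  # thermodynamic variables
    UM = "UM"  # units of measure
    CC = "CC"  # computational concepts
    BIND = "BIND"  # binding-process terms (annotation only)
    VARIANT = "VARIANT"  # amino-acid variants (annotation only)

    @property
    def scored(self) -> bool:
        return self in SCORED_CLASSES


SCORED_CLASSES = frozenset({TermClass.TC, TermClass.TV, TermClass.UM, TermClass.CC})
ALL_CLASSES = frozenset(TermClass)


@dataclass(frozen=True)
class LexiconEntry:
    """One term: its class, integer score, and raw-text regex (if any).

    ``match_on`` is ``"lemma"`` for concept words matched against the
    lemma stream and ``"raw"`` for regex matching on the raw unit text.
    """

    term_class: TermClass
    canonical: str
    score: int
    match_on: str  # "lemma" | "raw"
    pattern: Optional[str] = None  # regex source, compiled lazily

    def __post_init__(self) -> None:
        if self.match_on not in ("lemma", "raw"):
            raise ValueError(f"bad match_on: {self.match_on!r}")
        if self.match_on == "raw" and not self.pattern:
            raise ValueError(f"raw-matched entry {self.canonical!r} needs a pattern")
        if not self.term_class.scored and self.score != 0:
            raise ValueError(f"{self.term_class.value} entries are unscored")

    def compiled(self) -> "re.Pattern[str]":
        return _compile(self.pattern)


def _compile(pattern: str) -> "re.Pattern[str]":
    return _PATTERN_CACHE.setdefault(pattern, re.compile(pattern))


_PATTERN_CACHE: Dict[str, "re.Pattern[str]"] = {}


@dataclass
class Lexicon:
    """An ordered collection of :class:`LexiconEntry`, indexable by class."""

    entries: List[LexiconEntry] = field(default_factory=list)

    def by_class(self, term_class: TermClass) -> List[LexiconEntry]:
        return [e for e in self.entries if e.term_class is term_class]

    def score_of(self, canonical: str) -> int:
        for e in self.entries:
            if e.canonical == canonical:
                return e.score
        raise KeyError(canonical)

    # --- serialization: plain TSV, bit-exact round trip ---

    def to_tsv(self, path: Union[str, Path, None] = None) -> str:
        lines = ["class\tcanonical\tscore\tmatch_on\tpattern"]
        for e in self.entries:
            lines.append(
                f"{e.term_class.value}\t{e.canonical}\t{e.score}\t{e.match_on}\t{e.pattern or ''}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_tsv(cls, source: Union[str, Path]) -> "Lexicon":
        if isinstance(source, Path) or "\t" not in str(source):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        entries = []
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            klass, canonical, score, match_on, pattern = line.split("\t")
            entries.append(
                LexiconEntry(TermClass(klass), canonical, int(score), match_on, pattern or None)
            )
        return cls(entries=entries)


# Boundary lookarounds for symbol/unit matching: the character adjacent
# to the match must not be ASCII alphanumeric, so "ΔGunf" is rejected but
# "25°C" and "(kcal/mol)" are accepted where the entry allows digits.
_LB = r"(?<![A-Za-z0-9])"
_RB = r"(?![A-Za-z0-9])"
_LB_LETTER = r"(?<![A-Za-z])"  # allows a preceding digit (25°C)

# Delta spellings: the Greek character, a word-bounded ASCII d/D, or the
# spelled-out "delta". Double-delta likewise, including "dd"/"DD".
_DELTA = r"(?:Δ|[dD](?![eE][lL][tT][aA])|[dD][eE][lL][tT][aA] ?)"
_DDELTA = r"(?:ΔΔ|[dD][dD](?![eE][lL][tT][aA])|[dD][eE][lL][tT][aA] ?[dD][eE][lL][tT][aA] ?)"

_TV_SYMBOLS = ("Cp", "Tm", "UG", "GU", "G", "H", "T", "U")
_UM_ENERGY = ("kcal", "kJ")
_UM_AMOUNT = ("mole/°C", "mol/°C", "mol/K", "mol/M", "mole", "mol")

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val"
)

VARIANT_PATTERNS = (
    rf"{_LB}[{_AA1}]\d+[{_AA1}]{_RB}",
    rf"{_LB}(?i:(?:{_AA3})\d+(?:{_AA3})){_RB}",
)


def _word_pattern(term: str) -> str:
    # multiword CC/BIND terms are matched on lowercased, whitespace-
    # normalized text, so a single space joins the words
    return _LB + re.escape(term) + _RB


def build_default_lexicon() -> Lexicon:
    """The packaged default lexicon with the printed integer weights."""
    entries: List[LexiconEntry] = []

    for word in ("unfolding", "two-state", "denaturant", "dichroism", "midpoint"):
        entries.append(LexiconEntry(TermClass.TC, word, 1, "lemma"))

    for sym in ("Cp", "Tm"):
        entries.append(
            LexiconEntry(TermClass.TV, sym, 1, "raw", _LB + sym + _RB)
        )
    for sym in _TV_SYMBOLS:
        entries.append(
            LexiconEntry(TermClass.TV, f"Δ{sym}", 2, "raw", _LB + _DELTA + sym + _RB)
        )
        entries.append(
            LexiconEntry(TermClass.TV, f"ΔΔ{sym}", 3, "raw", _LB + _DDELTA + sym + _RB)
        )

    entries.append(
        LexiconEntry(TermClass.UM, "°C", 1, "raw", _LB_LETTER + r"(?:° ?C|degrees? C)" + _RB)
    )
    for energy in _UM_ENERGY:
        for amount in _UM_AMOUNT:
            canonical = f"{energy}/{amount}"
            pat = _LB + re.escape(canonical).replace("°", "° ?") + _RB
            entries.append(
                LexiconEntry(TermClass.UM, canonical, 2, "raw", f"(?i:{pat})")
            )

    cc_words = (
        "simulation", "molecular dynamics", "force field",
        "charmm", "gromacs", "amber", "pbsa", "gbsa", "predict",
    )
    for word in cc_words:
        entries.append(LexiconEntry(TermClass.CC, word, -1, "raw", _word_pattern(word)))
    entries.append(
        LexiconEntry(TermClass.CC, "md simulation", -2, "raw", _word_pattern("md simulation"))
    )

    for word in (
        "binding", "affinity", "dissociation", "interaction",
        "ppi", "protein-protein", "kcat/km",
    ):
        entries.append(LexiconEntry(TermClass.BIND, word, 0, "raw", _word_pattern(word)))

    for i, pat in enumerate(VARIANT_PATTERNS):
        entries.append(
            LexiconEntry(TermClass.VARIANT, f"variant[{i}]", 0, "raw", pat)
        )
    return Lexicon(entries=entries)


@dataclass(frozen=True)
class Match:
    """One term occurrence in a unit: class, canonical term, raw span."""

    term_class: TermClass
    canonical: str
    span: Tuple[int, int]  # half-open, 0-based, in the raw unit text
    matched_text: str


@dataclass
class MatchSet:
    """All matches found in one unit, scored-class overlaps resolved."""

    unit: TextUnit
    matches: List[Match] = field(default_factory=list)

    def scored(self) -> List[Match]:
        return [m for m in self.matches if m.term_class.scored]


def _candidates_for_entry(
    entry: LexiconEntry, unit: TextUnit, tokenized: TokenizedUnit
) -> Iterable[Match]:
    if entry.match_on == "lemma":
        for token, span in zip(tokenized.tokens, tokenized.raw_spans):
            if token == entry.canonical:
                yield Match(entry.term_class, entry.canonical, span,
                            unit.text[span[0]:span[1]])
        return
    text = unit.text
    if entry.term_class in (TermClass.CC, TermClass.BIND):
        text = text.lower()
    for m in entry.compiled().finditer(text):
        span = (m.start(), m.end())
        yield Match(entry.term_class, entry.canonical, span,
                    unit.text[span[0]:span[1]])


def _resolve_longest_leftmost(candidates: Sequence[Match]) -> List[Match]:
    """Greedy non-overlap selection: longest span first, ties leftmost."""
    ordered = sorted(
        candidates, key=lambda m: (-(m.span[1] - m.span[0]), m.span[0], m.canonical)
    )
    kept: List[Match] = []
    occupied: List[Tuple[int, int]] = []
    for m in ordered:
        a, b = m.span
        if any(a < y and x < b for x, y in occupied):
            continue
        kept.append(m)
        occupied.append((a, b))
    kept.sort(key=lambda m: m.span)
    return kept


def match_unit(
    unit: TextUnit,
    tokenized: TokenizedUnit,
    lex: Lexicon,
    enabled_classes: Union[Set[TermClass], frozenset] = SCORED_CLASSES,
) -> MatchSet:
    """Find every enabled-class term occurrence in one unit.

    Scored-class candidates are made mutually non-overlapping by the
    longest-first / leftmost rule; annotation-only matches (BIND,
    VARIANT) are reported as found and never enter the overlap
    resolution or the score.
    """
    scored_cands: List[Match] = []
    annot: List[Match] = []
    for entry in lex.entries:
        if entry.term_class not in enabled_classes:
            continue
        for m in _candidates_for_entry(entry, unit, tokenized):
            (scored_cands if entry.term_class.scored else annot).append(m)
    matches = _resolve_longest_leftmost(scored_cands)
    annot.sort(key=lambda m: m.span)
    matches.extend(annot)
    return MatchSet(unit=unit, matches=matches)


def find_variants(unit: TextUnit) -> List[Match]:
    """Amino-acid substitution mentions (``V31A``, ``Ala123Gly``).

    Only the 20 canonical residue codes qualify, so strings like
    ``B12X`` are not flagged.
    """
    out: List[Match] = []
    for pat in VARIANT_PATTERNS:
        for m in _compile(pat).finditer(unit.text):
            out.append(
                Match(TermClass.VARIANT, m.group(0), (m.start(), m.end()), m.group(0))
            )
    out.sort(key=lambda m: m.span)
    return out
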