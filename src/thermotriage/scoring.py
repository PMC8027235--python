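"""Per-unit and document-level scoring and the threshold classifier.

A unit's score is the sum of the scores of its matched terms *without
repetitions*: each canonical term contributes at most once per unit,
however many times it occurs there. Document-level quantities are the
total (sum over units), the maximum unit score (Max) and the mean unit
score (Mean); the mean is taken over units that contain at least one
scored match, so it is comparable across articles of very different
lengths.

Extraction is gated on the thermodynamic-concept class: when TC is
enabled and no TC word occurs anywhere in the document, the article is
considered out of domain and no terms are extracted at all (all scores
zero, ``gated_out`` set). Disabling TC (class-ablation variants)
disables the gate.

A document is classified positive when its active score (Max or Mean)
meets the threshold, inclusively: the default operating point is
Max >= 3.00 (the Mean variant uses 1.36).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import FrozenSet, List, Optional, Sequence, Tuple, Union

from .corpus import Document
from .lexicon import (
    SCORED_CLASSES,
    Lexicon,
    MatchSet,
    TermClass,
    build_default_lexicon,
    match_unit,
)
from .textprep import preprocess

__all__ = [
    "UnitScore",
    "DocumentScore",
    "ClassifierConfig",
    "DEFAULT_MAX_THRESHOLD",
    "DEFAULT_MEAN_THRESHOLD",
    "score_unit",
    "score_document",
    "classify",
]

# Operating points from threshold optimization (MCC-maximizing) for the
# two scoring modes.
DEFAULT_MAX_THRESHOLD = 3.00
DEFAULT_MEAN_THRESHOLD = 1.36


@dataclass(frozen=True)
class UnitScore:
    unit_index: int
    score: int
    contributing_terms: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.score != sum(s for _, s in self.contributing_terms):
            raise ValueError("score must equal the sum of contributing terms")


@dataclass
class DocumentScore:
    doc_id: Union[str, object]
    total: int
    max_score: int
    mean_score: float
    n_units_scored: int
    unit_scores: List[UnitScore] = field(default_factory=list)
    gated_out: bool = False

    def active(self, mode: str) -> float:
        if mode == "Max":
            return float(self.max_score)
        if mode == "Mean":
            return float(self.mean_score)
        raise ValueError(f"unknown scoring mode: {mode!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Scoring mode, threshold and the enabled term classes."""

    mode: str = "Max"
    threshold: float = DEFAULT_MAX_THRESHOLD
    enabled_classes: FrozenSet[TermClass] = SCORED_CLASSES

    def __post_init__(self) -> None:
        if self.mode not in ("Max", "Mean"):
            raise ValueError(f"mode must be 'Max' or 'Mean', got {self.mode!r}")


def score_unit(ms: MatchSet, lex: Lexicon) -> UnitScore:
    """Sum scored-match scores, each canonical term counted once.

    Annotation-only matches (BIND, VARIANT) never contribute. The score
    can be negative: computational-concept matches are penalties.
    """
    seen = {}
    for m in ms.scored():
        if m.canonical not in seen:
            seen[m.canonical] = lex.score_of(m.canonical)
    contributing = tuple(seen.items())
    return UnitScore(
        unit_index=ms.unit.index,
        score=sum(seen.values()),
        contributing_terms=contributing,
    )


def _match_all(doc: Document, lex: Lexicon, enabled: FrozenSet[TermClass],
               stopwords=None) -> List[MatchSet]:
    out = []
    for unit in doc.units:
        tok = preprocess(unit, stopwords)
        out.append(match_unit(unit, tok, lex, enabled))
    return out


def score_document(
    doc: Document,
    lex: Optional[Lexicon] = None,
    cfg: Optional[ClassifierConfig] = None,
    stopwords=None,
    return_matches: bool = False,
):
    """Score every unit of a document and aggregate.

    Returns a :class:`DocumentScore`; with ``return_matches=True`` also
    returns the per-unit :class:`MatchSet` list (for report rendering).
    """
    if lex is None:
        lex = build_default_lexicon()
    if cfg is None:
        cfg = ClassifierConfig()
    enabled = frozenset(cfg.enabled_classes)

    matchsets: List[MatchSet] = []
    gated_out = False
    if TermClass.TC in enabled:
        tc_only = frozenset({TermClass.TC})
        has_tc = any(
            match_unit(u, preprocess(u, stopwords), lex, tc_only).matches
            for u in doc.units
        )
        gated_out = not has_tc

    if gated_out:
        unit_scores = [UnitScore(u.index, 0) for u in doc.units]
        ds = DocumentScore(doc.id, 0, 0, 0.0, 0, unit_scores, gated_out=True)
        matchsets = [MatchSet(unit=u) for u in doc.units]
    else:
        matchsets = _match_all(doc, lex, enabled, stopwords)
        unit_scores = [score_unit(ms, lex) for ms in matchsets]
        scored_units = [us for us in unit_scores if us.contributing_terms]
        total = sum(us.score for us in unit_scores)
        n_scored = len(scored_units)
        max_score = max((us.score for us in scored_units), default=0)
        mean_score = float(Fraction(total, n_scored)) if n_scored else 0.0
        ds = DocumentScore(doc.id, total, max_score, mean_score, n_scored, unit_scores)

    if return_matches:
        return ds, matchsets
    return ds


def classify(ds: DocumentScore, cfg: ClassifierConfig) -> str:
    """``"positive"`` iff the active score meets the threshold (>=)."""
    return "positive" if ds.active(cfg.mode) >= cfg.threshold else "negative"


def score_documents(
    docs: Sequence[Document],
    lex: Optional[Lexicon] = None,
    cfg: Optional[ClassifierConfig] = None,
) -> List[DocumentScore]:
    if lex is None:
        lex = build_default_lexicon()
    if cfg is None:
        cfg = ClassifierConfig()
    return [score_document(d, lex, cfg) for d in docs]
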