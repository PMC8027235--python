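"""Concept-word selection by binomial document-frequency enrichment.

The scored concept vocabulary was chosen by comparing, word by word, the
number of positive-corpus documents containing the word against the
document frequency expected from a background corpus. Significance is
the binomial survival probability P(X >= k_pos) with X ~ Binomial(n_pos,
p_bg), where p_bg is the word's background document probability; words
are ranked by ascending p-value and the top of the ranking supplies the
concept list.

Counting is presence/absence per document (document frequency), not
term frequency. A word absent from the background gets the smoothed
background probability 1/(n_bg + 1) so its p-value stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, List, Sequence, Set, Union

from scipy import stats

from .corpus import Document
from .textprep import preprocess

__all__ = ["WordStat", "binomial_sf", "rank_words", "document_token_set", "write_ranking"]


@dataclass(frozen=True)
class WordStat:
    """Enrichment record for one word."""

    word: str
    k_pos: int
    n_pos: int
    k_bg: int
    n_bg: int
    p_bg: float
    p_value: float


def binomial_sf(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) (survival function, inclusive).

    Note the inclusive convention: this is ``1 - CDF(k - 1)``, computed
    through the distribution's survival function for numerical
    stability at large ``n``.
    """
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"require 0 <= p <= 1, got p={p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def document_token_set(doc: Document, stopwords=None) -> FrozenSet[str]:
    """The distinct lemmas of a document (its document-frequency unit)."""
    tokens: Set[str] = set()
    for unit in doc.units:
        tokens.update(preprocess(unit, stopwords).tokens)
    return frozenset(tokens)


def rank_words(
    pos_docs: Sequence[Set[str]],
    bg_docs: Sequence[Set[str]],
    min_bg_count: int = 0,
) -> List[WordStat]:
    """Rank every positive-corpus word by binomial enrichment p-value.

    Parameters
    ----------
    pos_docs, bg_docs
        Per-document distinct-lemma sets for the positive and background
        corpora.
    min_bg_count
        Drop words observed in fewer than this many background
        documents (0 keeps everything).

    Returns
    -------
    list of WordStat, ascending by p-value; ties broken by descending
    positive count, then alphabetically.
    """
    if not pos_docs or not bg_docs:
        raise ValueError("both corpora must be non-empty")
    n_pos, n_bg = len(pos_docs), len(bg_docs)
    vocab = set()
    for s in pos_docs:
        vocab.update(s)
    stats_out: List[WordStat] = []
    for word in vocab:
        k_pos = sum(1 for s in pos_docs if word in s)
        k_bg = sum(1 for s in bg_docs if word in s)
        if k_bg < min_bg_count:
            continue
        p_bg = k_bg / n_bg if k_bg > 0 else 1.0 / (n_bg + 1)
        stats_out.append(
            WordStat(word, k_pos, n_pos, k_bg, n_bg, p_bg,
                     binomial_sf(k_pos, n_pos, p_bg))
        )
    stats_out.sort(key=lambda w: (w.p_value, -w.k_pos, w.word))
    return stats_out


def write_ranking(ranking: Sequence[WordStat], path: Union[str, Path]) -> None:
    """TSV dump: word, counts, background probability, p-value, rank."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tk_pos\tn_pos\tk_bg\tn_bg\tp_bg\tp_value\trank\n")
        for rank, w in enumerate(ranking, 1):
            fh.write(
                f"{w.word}\t{w.k_pos}\t{w.n_pos}\t{w.k_bg}\t{w.n_bg}\t"
                f"{w.p_bg:.6g}\t{w.p_value:.6g}\t{rank}\n"
            )
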