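"""Reading full-text article HTML and identifier/label lists.

Articles are consumed as PMC-style full-text HTML pages. The only
structure this package cares about is the ordered sequence of paragraph
(``<p>``) and table (``<table>``) elements: each becomes one
:class:`TextUnit`, and everything downstream (matching, scoring,
reporting) operates on those units.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

import lxml.etree
import lxml.html

logger = logging.getLogger(__name__)

__all__ = [
    "ArticleID",
    "TextUnit",
    "Document",
    "parse_article_html",
    "parse_article_file",
    "read_id_list",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class ArticleID:
    """An article identifier: a PMCID, PMID or DOI."""

    scheme: str  # one of {"PMCID", "PMID", "DOI"}
    value: str

    _SCHEMES = ("PMCID", "PMID", "DOI")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown identifier scheme: {self.scheme!r}")
        if not self.value:
            raise ValueError("identifier value must be non-empty")
        if self.scheme == "PMCID":
            if not (self.value.startswith("PMC") and self.value[3:].isdigit()):
                raise ValueError(f"malformed PMCID: {self.value!r}")

    @classmethod
    def parse(cls, token: str) -> "ArticleID":
        """Infer the scheme of a bare identifier string.

        ``PMC`` prefix -> PMCID; all digits -> PMID; contains ``/`` -> DOI.
        """
        token = token.strip()
        if token.startswith("PMC") and token[3:].isdigit():
            return cls("PMCID", token)
        if token.isdigit():
            return cls("PMID", token)
        if "/" in token:
            return cls("DOI", token)
        raise ValueError(f"cannot classify identifier: {token!r}")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.value


@dataclass(frozen=True)
class TextUnit:
    """One extracted paragraph or table, as whitespace-normalized text."""

    kind: str  # "paragraph" | "table"
    index: int  # 0-based position within the document (kind-agnostic)
    text: str

    def __post_init__(self) -> None:
        if self.kind not in ("paragraph", "table"):
            raise ValueError(f"unknown unit kind: {self.kind!r}")
        if self.text != normalize_text(self.text):
            raise ValueError("unit text must be whitespace-normalized")


@dataclass
class Document:
    """An article: an identifier plus its ordered text units."""

    id: Union[ArticleID, str]
    units: List[TextUnit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)


def normalize_text(text: str) -> str:
    """Collapse whitespace runs, strip ends, compose Unicode (NFC)."""
    return unicodedata.normalize("NFC", " ".join(text.split()))


def _element_text(el: lxml.html.HtmlElement) -> str:
    # text_content() concatenates descendant text nodes with no inserted
    # separator, so inline markup such as a subscripted U after a Delta-G
    # symbol reconstructs as the contiguous token the matcher expects.
    return normalize_text(el.text_content())


def _table_text(table: lxml.html.HtmlElement) -> str:
    rows = table.findall(".//tr")
    if not rows:
        return _element_text(table)
    cells: List[str] = []
    for row in rows:
        for cell in row.iter():
            if cell.tag in ("td", "th"):
                t = _element_text(cell)
                if t:
                    cells.append(t)
    # caption / free text outside rows is rare; cells carry the content
    return normalize_text(" ".join(cells))


def _has_ancestor(el: lxml.html.HtmlElement, tag: str) -> bool:
    parent = el.getparent()
    while parent is not None:
        if parent.tag == tag:
            return True
        parent = parent.getparent()
    return False


def parse_article_html(html_text: str, doc_id: Union[ArticleID, str] = "") -> Document:
    """Extract the ordered paragraph/table units from an HTML page.

    One :class:`TextUnit` is produced per outermost ``<p>`` element and
    per outermost ``<table>`` element, in document order. Paragraphs
    nested inside tables belong to the table unit only, so no text is
    counted twice. The parser is tolerant of malformed markup;
    unparseable input yields an empty :class:`Document` and a logged
    warning rather than an exception.
    """
    units: List[TextUnit] = []
    if html_text and html_text.strip():
        try:
            root = lxml.html.fromstring(html_text)
        except (lxml.etree.ParserError, ValueError) as exc:
            logger.warning("unparseable HTML for %s: %s", doc_id, exc)
            return Document(id=doc_id, units=[])
        idx = 0
        for el in root.iter():
            if el.tag == "p":
                if _has_ancestor(el, "table") or _has_ancestor(el, "p"):
                    continue
                units.append(TextUnit("paragraph", idx, _element_text(el)))
                idx += 1
            elif el.tag == "table":
                if _has_ancestor(el, "table"):
                    continue
                units.append(TextUnit("table", idx, _table_text(el)))
                idx += 1
    return Document(id=doc_id, units=units)


def parse_article_file(path: Union[str, Path]) -> Document:
    path = Path(path)
    return parse_article_html(path.read_text(encoding="utf-8"), doc_id=path.stem)


def read_id_list(path: Union[str, Path]) -> List[ArticleID]:
    """Read one identifier per line; blank lines and ``#`` comments skipped."""
    ids: List[ArticleID] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        try:
            ids.append(ArticleID.parse(token))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return ids


def read_labels(path: Union[str, Path]) -> dict:
    """Read a labeled-corpus TSV of ``id<TAB>label`` rows.

    Labels are normalized to ``pos`` / ``neg``. A header row starting
    with ``id`` is skipped.
    """
    labels = {}
    alias = {"pos": "pos", "positive": "pos", "1": "pos",
             "neg": "neg", "negative": "neg", "0": "neg"}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
        if lineno == 1 and parts[0].lower() == "id":
            continue
        key = parts[1].strip().lower()
        if key not in alias:
            raise ValueError(f"{path}:{lineno}: unknown label {parts[1]!r}")
        labels[parts[0].strip()] = alias[key]
    return labels


def write_labels(labels: Iterable[tuple], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\n")
        for doc_id, label in labels:
            fh.write(f"{doc_id}\t{label}\n")
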