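"""Annotated-HTML report: highlighted terms and per-unit scores.

Mirrors the curation view: thermodynamic terms (concepts, variables,
units of measure) in red, computational concepts in blue, amino-acid
variant mentions in green, each unit annotated with its score, and a
header carrying the document's total and maximum scores. The annotation
layer never alters the unit text — stripping the tags recovers it
exactly.
"""

from __future__ import annotations

import html as html_mod
from typing import List, Sequence

from .corpus import Document
from .lexicon import Match, MatchSet, TermClass
from .scoring import DocumentScore

__all__ = ["render_report"]

_CSS = """
body { font-family: sans-serif; max-width: 60em; margin: 2em auto; }
.unit { margin: 1em 0; padding: 0.5em; border-left: 3px solid #ccc; }
.unit-score { color: #555; font-size: 0.85em; }
.thermo { color: #c00; font-weight: bold; }
.comp { color: #00c; font-weight: bold; }
.variant { color: #080; font-weight: bold; }
"""

_CLASS_CSS = {
    TermClass.TC: "thermo",
    TermClass.TV: "thermo",
    TermClass.UM: "thermo",
    TermClass.CC: "comp",
    TermClass.VARIANT: "variant",
    TermClass.BIND: "bind",
}


def _render_unit_text(text: str, matches: Sequence[Match]) -> str:
    # scored matches are non-overlapping by construction; annotation-only
    # matches are added where they do not collide with an earlier span
    chosen: List[Match] = []
    occupied: List[tuple] = []
    for m in sorted(matches, key=lambda m: (not m.term_class.scored, m.span)):
        a, b = m.span
        if any(a < y and x < b for x, y in occupied):
            continue
        chosen.append(m)
        occupied.append((a, b))
    chosen.sort(key=lambda m: m.span)

    parts: List[str] = []
    pos = 0
    for m in chosen:
        a, b = m.span
        parts.append(html_mod.escape(text[pos:a], quote=False))
        css = _CLASS_CSS.get(m.term_class, "")
        parts.append(
            f'<span class="{css}" title="{html_mod.escape(m.canonical)}">'
            f"{html_mod.escape(text[a:b], quote=False)}</span>"
        )
        pos = b
    parts.append(html_mod.escape(text[pos:], quote=False))
    return "".join(parts)


def render_report(
    doc: Document, ds: DocumentScore, matchsets: Sequence[MatchSet]
) -> str:
    """Render one document as a standalone annotated HTML page."""
    out: List[str] = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{html_mod.escape(str(doc.id))}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>{html_mod.escape(str(doc.id))}</h1>",
        f"<p class='summary'>total score: <b>{ds.total}</b>, "
        f"max paragraph/table score: <b>{ds.max_score}</b>, "
        f"mean: <b>{ds.mean_score:.2f}</b>"
        + (" — <i>no thermodynamic concept word found; extraction skipped</i>"
           if ds.gated_out else "")
        + "</p>",
    ]
    scores = {us.unit_index: us.score for us in ds.unit_scores}
    for unit, ms in zip(doc.units, matchsets):
        body = _render_unit_text(unit.text, ms.matches)
        out.append(
            f"<div class='unit'><span class='unit-score'>"
            f"[{unit.kind} {unit.index}] score {scores.get(unit.index, 0)}</span>"
            f"<br>{body}</div>"
        )
    out.append("</body></html>")
    return "".join(out)
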