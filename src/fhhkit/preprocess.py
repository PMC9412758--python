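"""Concatenate structured FHH fields with the comment into marked text.

The comment field of an FHH entry cannot be interpreted in isolation: it
supplements or corrects the coded fields it sits next to.  The extractor
therefore runs over a single concatenated string in which every structured
value is wrapped in double curly brackets (``{{CANCER}}``), so downstream
rules can tell a coded value from narrative text.  Field order is
condition, comment, family member, age of onset; a null structured value
renders as an empty marker ``{{}}``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import FHHEntry, MarkedText

__all__ = ["combine_fields", "split_sentences", "Segment", "strip_markers"]

#: terminal "." after these tokens never ends a sentence (telegraphic
#: clinical abbreviations)
_ABBREVIATIONS = {"dx", "ca", "yr", "yrs", "dr", "mr", "mrs", "st", "approx"}


def combine_fields(entry: FHHEntry) -> MarkedText:
    """Render one entry as marked concatenated text.

    ``{{condition}} comment {{relative}} {{onset}}`` joined by single
    spaces; null structured fields become empty ``{{}}`` markers so every
    field position is represented.
    """
    cond = entry.condition_code or ""
    rel = entry.relative_code or ""
    onset = "" if entry.onset_age is None else str(entry.onset_age)
    comment = entry.comment or ""

    parts = []
    spans = []
    pos = 0

    def marker(value: str, name: str) -> None:
        nonlocal pos
        token = "{{" + value + "}}"
        parts.append(token)
        spans.append((pos, pos + len(token), name))
        pos += len(token)

    marker(cond, "condition")
    parts.append(" ")
    pos += 1
    comment_span = (pos, pos + len(comment))
    parts.append(comment)
    pos += len(comment)
    parts.append(" ")
    pos += 1
    marker(rel, "relative")
    parts.append(" ")
    pos += 1
    marker(onset, "onset")

    return MarkedText(text="".join(parts), source_spans=tuple(spans), comment_span=comment_span)


def strip_markers(marked: MarkedText) -> str:
    """Recover the verbatim comment by removing markers and joining spaces."""
    s, e = marked.comment_span
    return marked.text[s:e]


@dataclass(frozen=True)
class Segment:
    """A sentence-level slice of the marked text (half-open char span)."""

    start: int
    end: int
    text: str
    index: int


def split_sentences(marked: MarkedText) -> list[Segment]:
    """Split the marked text into sentence segments.

    Boundaries fall after ``. `` (period + space), ``;`` and newline, but
    never inside a ``{{ }}`` marked region, after a known abbreviation, or
    inside a decimal number.  Segments tile the text exactly, so total
    character count is preserved.
    """
    text = marked.text
    boundaries: list[int] = []
    for i, ch in enumerate(text):
        if marked.in_marked_region(i, i + 1):
            continue
        if ch in ";\n":
            boundaries.append(i + 1)
        elif ch == "." and i + 1 < len(text) and text[i + 1] == " ":
            # reject decimals and abbreviation periods
            if i > 0 and text[i - 1].isdigit() and i + 2 < len(text) and text[i + 2].isdigit():
                continue
            j = i
            while j > 0 and (text[j - 1].isalnum() or text[j - 1] == "-"):
                j -= 1
            if text[j:i].lower() in _ABBREVIATIONS:
                continue
            boundaries.append(i + 1)

    segments: list[Segment] = []
    prev = 0
    for b in boundaries:
        if b > prev:
            segments.append(Segment(prev, b, text[prev:b], len(segments)))
            prev = b
    if prev < len(text) or not segments:
        segments.append(Segment(prev, len(text), text[prev:], len(segments)))
    return segments
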