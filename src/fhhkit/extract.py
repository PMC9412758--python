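"""Entity extraction from marked FHH text.

Step one of the pipeline: match each sentence segment against the keyword
lexicon (longest match, case-insensitive), recognize onset expressions and
multiplicity prefixes with small pattern grammars, tag values inside
``{{ }}`` markers as structural, and apply context rules (exclusion
contexts such as "lives with her daughter", uncertainty hedges) before
classification fills in relative codes, sex and family side.
"""

from __future__ import annotations

import re
from typing import Optional

from .core import (
    CANCER_SITES,
    CONDITION_LABELS,
    Entity,
    EntityLabel,
    MarkedText,
    OnsetKind,
    OnsetValue,
    Sex,
    Side,
    Status,
)
from .lexicon import Lexicon
from .preprocess import Segment, split_sentences

__all__ = [
    "match_lexicon",
    "apply_context_rules",
    "classify_entities",
    "extract_entities",
    "parse_onset",
    "parse_multiplicity",
]

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
}

_MULT_PREFIX = re.compile(
    r"(?:(?P<num>\d+)\s*[x×]\s*|(?P<word>one|two|three|four|five|six|seven|eight|nine|ten)\s+)",
    re.IGNORECASE,
)
_MULT_ANY = re.compile(
    r"(?:(\d+)\s*[x×]|[x×]\s*(\d+)|\b(one|two|three|four|five|six|seven|eight|nine|ten)\b)",
    re.IGNORECASE,
)

_DECEASED_RE = re.compile(
    r"\b(?:deceased|died|passed(?:\s+away)?)\s+(?:at\s+)?(?:age\s+)?(?:of\s+)?(\d{1,3})"
    r"(?:\s*(?:years?|yrs?)(?:\s+old)?)?",
    re.IGNORECASE,
)
_RANGE_RE = re.compile(
    r"\b(?:in\s+(?:his|her|their)\s+)?(?:the\s+)?(early|late|mid)?[\s-]*(\d0)'?s\b",
    re.IGNORECASE,
)
_PERIOD_RE = re.compile(r"\b(?:in\s+)?(19\d{2}|20\d{2})\b", re.IGNORECASE)
_STRING_RE = re.compile(
    r"\b(?:\d+\s+(?:years?|yrs?)\s+ago|postmenstruation|premenopausal|postmenopausal|"
    r"as\s+a\s+child|in\s+childhood|young|recently|last\s+year)\b",
    re.IGNORECASE,
)
_AGE_RE = re.compile(
    r"\b(?:(?:dx|diagnosed|dx'd)\s+)?(?:at\s+)?(?:age\s+)?(?:of\s+)?(\d{1,3})\b",
    re.IGNORECASE,
)
_SIDE_PREFIX = re.compile(
    r"(?P<cue>maternal|paternal|mother'?s|father'?s)\s+$", re.IGNORECASE
)

_WORD_CHARS = re.compile(r"[A-Za-z0-9]")


def parse_onset(span_text: str) -> OnsetValue:
    """Normalize an onset mention to an :class:`OnsetValue`.

    Exact ages map to AGE; decade phrases to RANGE with decade-derived
    bounds ("early 50s" -> [50, 54], "late 50s" -> [55, 59], bare "50s" ->
    [50, 59]); four-digit years to PERIOD; anything else falls back to
    STRING.
    """
    text = span_text.strip()
    m = _RANGE_RE.search(text)
    if m:
        qual = (m.group(1) or "").lower()
        decade = int(m.group(2))
        if qual == "early":
            return OnsetValue(OnsetKind.RANGE, decade, decade + 4, raw=text)
        if qual == "late":
            return OnsetValue(OnsetKind.RANGE, decade + 5, decade + 9, raw=text)
        if qual == "mid":
            return OnsetValue(OnsetKind.RANGE, decade + 3, decade + 6, raw=text)
        return OnsetValue(OnsetKind.RANGE, decade, decade + 9, raw=text)
    m = _PERIOD_RE.fullmatch(text) or _PERIOD_RE.search(text)
    if m and len(m.group(1)) == 4:
        return OnsetValue(OnsetKind.PERIOD, raw=text)
    m = _AGE_RE.search(text)
    if m:
        age = int(m.group(1))
        if 0 <= age <= 120:
            return OnsetValue(OnsetKind.AGE, age, age, raw=text)
    return OnsetValue(OnsetKind.STRING, raw=text)


def parse_multiplicity(fm_text: str) -> int:
    """Number of individuals a family-member mention denotes (default 1).

    Recognizes ``2×``/``2 x``/``x2`` affixes and number words up to ten;
    an explicit zero is treated as one.
    """
    m = _MULT_ANY.search(fm_text)
    if not m:
        return 1
    n = None
    if m.group(1):
        n = int(m.group(1))
    elif m.group(2):
        n = int(m.group(2))
    elif m.group(3):
        n = _NUMBER_WORDS[m.group(3).lower()]
    if not n:
        import logging

        logging.getLogger(__name__).warning("multiplicity 0 in %r treated as 1", fm_text)
        return 1
    return n


def _left_boundary(text: str, pos: int) -> bool:
    return pos <= 0 or not _WORD_CHARS.match(text[pos - 1])


def _right_boundary(text: str, pos: int) -> bool:
    return pos >= len(text) or not _WORD_CHARS.match(text[pos])


def _match_terms(lexicon: Lexicon, text: str, offset: int, consumed: list[tuple[int, int]],
                 segment_index: int, structural: bool) -> list[Entity]:
    """Greedy longest-match lexicon scan over ``text`` (global offsets)."""
    low = text.lower()
    hits: list[Entity] = []
    i = 0
    while i < len(low):
        if not _WORD_CHARS.match(low[i]) or not _left_boundary(low, i):
            i += 1
            continue
        best = None
        for term in lexicon.sorted_terms:
            if low.startswith(term, i) and _right_boundary(low, i + len(term)):
                best = term
                break  # sorted longest-first
        if best is None:
            i += 1
            continue
        start, end = offset + i, offset + i + len(best)
        if any(s < end and start < e for s, e in consumed):
            i += len(best)
            continue
        le = lexicon.lookup(best)
        ent = Entity(
            start=start,
            end=end,
            surface=text[i : i + len(best)],
            label=le.label,
            is_structural=structural,
            code=le.normalized,
            side=le.side if le.label is EntityLabel.FAMILYMEMBER else Side.UNKNOWN,
            sex=le.sex,
            segment_index=segment_index,
        )
        hits.append(ent)
        consumed.append((start, end))
        i += len(best)
    return hits


def _structural_entities(segment: Segment, marked: MarkedText, lexicon: Lexicon,
                         consumed: list[tuple[int, int]]) -> list[Entity]:
    """Entities for marked-region values that fall inside this segment."""
    out: list[Entity] = []
    for s, e, field_name in marked.source_spans:
        if not (segment.start <= s and e <= segment.end):
            continue
        inner_start, inner_end = s + 2, e - 2
        value = marked.text[inner_start:inner_end]
        consumed.append((s, e))
        if not value.strip():
            continue
        if field_name == "condition":
            norm = lexicon.normalize_condition_code(value)
            if norm is None:
                continue  # non-cancer / unrecognized code: no condition entity
            if norm == "CANCER":
                label = EntityLabel.CANCER
            elif norm in EntityLabel.__members__ and EntityLabel[norm] in CANCER_SITES:
                label = EntityLabel[norm]
            elif norm in {"LYNCH", "COWDEN", "LI_FRAUMENI", "FAP", "SERRATED_POLYPOSIS", "POLYPOSIS"}:
                label = EntityLabel.SYNDROME
            else:
                label = EntityLabel.GENE_MUT
            out.append(
                Entity(inner_start, inner_end, value, label, is_structural=True,
                       code=norm, segment_index=segment.index)
            )
        elif field_name == "relative":
            code = lexicon.normalize_relative_code(value)
            le = lexicon.lookup(value.strip().lower().replace("_", " ").replace("-", " "))
            out.append(
                Entity(
                    inner_start, inner_end, value, EntityLabel.FAMILYMEMBER,
                    is_structural=True, code=code or value.strip().upper(),
                    side=le.side if le else Side.UNKNOWN,
                    sex=le.sex if le else Sex.UNKNOWN,
                    segment_index=segment.index,
                )
            )
        elif field_name == "onset":
            if value.strip().isdigit():
                age = int(value.strip())
                out.append(
                    Entity(inner_start, inner_end, value, EntityLabel.ONSET_AGE,
                           is_structural=True, segment_index=segment.index,
                           onset=OnsetValue(OnsetKind.AGE, age, age, raw=value.strip()))
                )
    return out


def _onset_entities(segment: Segment, consumed: list[tuple[int, int]]) -> list[Entity]:
    """Pattern-matched onset and deceased-age mentions in narrative text."""
    out: list[Entity] = []
    text, off = segment.text, segment.start

    def take(m: re.Match, label: EntityLabel, onset: Optional[OnsetValue]) -> bool:
        start, end = off + m.start(), off + m.end()
        if any(s < end and start < e for s, e in consumed):
            return False
        consumed.append((start, end))
        out.append(Entity(start, end, m.group(0), label, onset=onset,
                          segment_index=segment.index))
        return True

    for m in _DECEASED_RE.finditer(text):
        take(m, EntityLabel.DECEASED_AGE,
             OnsetValue(OnsetKind.AGE, int(m.group(1)), int(m.group(1)), raw=m.group(0)))
    for m in _RANGE_RE.finditer(text):
        take(m, EntityLabel.ONSET_RANGE, parse_onset(m.group(0)))
    for m in _PERIOD_RE.finditer(text):
        take(m, EntityLabel.ONSET_PERIOD, parse_onset(m.group(0)))
    for m in _STRING_RE.finditer(text):
        take(m, EntityLabel.ONSET_STRING, OnsetValue(OnsetKind.STRING, raw=m.group(0)))
    for m in _AGE_RE.finditer(text):
        age = int(m.group(1))
        if 0 <= age <= 120:
            # span only the digits, matching how annotators mark bare ages
            dm = re.search(r"\d{1,3}", m.group(0))
            start = off + m.start() + dm.start()
            end = start + len(dm.group(0))
            if any(s < end and start < e for s, e in consumed):
                continue
            consumed.append((start, end))
            out.append(Entity(start, end, dm.group(0), EntityLabel.ONSET_AGE,
                              onset=OnsetValue(OnsetKind.AGE, age, age, raw=m.group(0)),
                              segment_index=segment.index))
    return out


def match_lexicon(segment: Segment, marked: MarkedText, lexicon: Lexicon) -> list[Entity]:
    """Longest-match lexicon and pattern extraction for one segment.

    Marked-region values are matched through the code tables and tagged
    structural immediately; narrative text goes through the term lexicon
    and the onset grammars.  A multiplicity affix adjacent to a family
    member ("2× sisters") is folded into the family-member span.
    """
    consumed: list[tuple[int, int]] = []
    # side-only phrases ("father side") are family-side features, not
    # family-member mentions, and override phrases ("no cancer") negate
    # rather than assert a condition: reserve their spans before matching
    low_seg = segment.text.lower()
    reserved = list(lexicon.side_only_phrases) + list(lexicon.override_terms)
    for phrase in sorted(reserved, key=len, reverse=True):
        idx = low_seg.find(phrase)
        while idx >= 0:
            s, e = segment.start + idx, segment.start + idx + len(phrase)
            if not any(cs < e and s < ce for cs, ce in consumed):
                consumed.append((s, e))
            idx = low_seg.find(phrase, idx + 1)
    entities = _structural_entities(segment, marked, lexicon, consumed)
    entities.extend(_match_terms(lexicon, segment.text, segment.start, consumed,
                                 segment.index, structural=False))
    # widen family-member spans over multiplicity prefixes / side cues
    for ent in entities:
        if ent.label is not EntityLabel.FAMILYMEMBER or ent.is_structural:
            continue
        rel = ent.start - segment.start
        prefix = segment.text[:rel]
        m = _MULT_PREFIX.search(prefix)
        if m and m.end() == len(prefix):
            ent.start = segment.start + m.start()
            ent.surface = segment.text[m.start() : ent.end - segment.start]
            ent.multiplicity = parse_multiplicity(ent.surface)
            consumed.append((ent.start, ent.end))
        sm = _SIDE_PREFIX.search(segment.text[: ent.start - segment.start])
        if sm:
            cue = sm.group("cue").lower()
            ent.side = Side.PATERNAL if cue.startswith(("pat", "fat")) else Side.MATERNAL
            ent.start = segment.start + sm.start()
            ent.surface = marked.text[ent.start : ent.end]
    entities.extend(_onset_entities(segment, consumed))
    entities.sort(key=lambda e: (e.start, -(e.end - e.start)))
    return _resolve_overlaps(entities)


def _resolve_overlaps(entities: list[Entity]) -> list[Entity]:
    """Longest match wins among same-label overlaps; leftmost breaks ties."""
    kept: list[Entity] = []
    for ent in sorted(entities, key=lambda e: (-(e.end - e.start), e.start)):
        clash = any(
            k.label is ent.label and k.start < ent.end and ent.start < k.end for k in kept
        )
        if not clash:
            kept.append(ent)
    kept.sort(key=lambda e: e.start)
    return kept


def apply_context_rules(entities: list[Entity], segment: Segment,
                        marked: MarkedText, lexicon: Lexicon) -> list[Entity]:
    """Structural tagging, exclusion contexts and uncertainty hedges.

    A family member mentioned after an exclusion trigger ("lives with her
    daughter") is marked IGNORED; an uncertainty cue anywhere in the
    segment flags every condition entity in that segment.
    """
    low = segment.text.lower()
    for ent in entities:
        if marked.in_marked_region(ent.start, ent.end):
            ent.is_structural = True
    for trigger in lexicon.exclusion_triggers:
        idx = low.find(trigger)
        while idx >= 0:
            trig_end = segment.start + idx + len(trigger)
            for ent in entities:
                if ent.label is EntityLabel.FAMILYMEMBER and not ent.is_structural \
                        and ent.start >= trig_end:
                    ent.status = Status.IGNORED
                    ent.ignore_reason = f"exclusion context: {trigger!r}"
            idx = low.find(trigger, idx + 1)
    if any(cue in low for cue in lexicon.uncertainty_cues):
        for ent in entities:
            if ent.label in CONDITION_LABELS and ent.segment_index == segment.index:
                ent.uncertainty = True
    return entities


def classify_entities(entities: list[Entity], lexicon: Lexicon) -> list[Entity]:
    """Entry-level classification after per-segment context rules.

    Partitions family members into structural vs comment-derived classes
    (``is_structural`` carries the distinction) and refines a generic
    structural CANCER when the comment names the site: the site-subtype
    entity carries the condition forward and the generic code is retired.
    """
    generic = [e for e in entities
               if e.label is EntityLabel.CANCER and e.is_structural and e.active]
    sites = [e for e in entities
             if e.label in CANCER_SITES and not e.is_structural and e.active]
    if generic and sites:
        for g in generic:
            g.status = Status.IGNORED
            g.ignore_reason = "site refined by comment"
    # drop comment-derived generic "cancer"/"ca" tokens that merely restate an
    # adjacent site term ("colon ca" is one entity already; a standalone
    # trailing "cancer" next to a site span adds nothing)
    for e in entities:
        if e.label is EntityLabel.CANCER and not e.is_structural and e.active:
            near_site = any(
                s.segment_index == e.segment_index and s.active
                and (abs(s.end - e.start) <= 1 or abs(e.end - s.start) <= 1)
                for s in entities if s.label in CANCER_SITES
            )
            if near_site:
                e.status = Status.IGNORED
                e.ignore_reason = "generic term adjacent to site"
    return entities


def extract_entities(marked: MarkedText, lexicon: Lexicon) -> tuple[list[Entity], list[Segment]]:
    """Run segmentation, lexicon matching, context rules and classification."""
    segments = split_sentences(marked)
    entities: list[Entity] = []
    for seg in segments:
        segment_entities = match_lexicon(seg, marked, lexicon)
        apply_context_rules(segment_entities, seg, marked, lexicon)
        entities.extend(segment_entities)
    classify_entities(entities, lexicon)
    return entities, segments
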