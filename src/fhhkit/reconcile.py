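"""Entity reconciliation between structured-field and comment-derived mentions.

The comment field of an FHH entry may supplement, refine, or contradict
the coded fields.  Eight ordered heuristics resolve these conflicts by
flipping entity statuses (losers become IGNORED, never deleted), adding
features, inferring onsets from deceased ages, and expanding multiplicity
mentions ("2× sisters") into separate family-member instances:

R1  a colorectal-cancer syndrome in the comment overrides a structured
    colon-cancer code;
R2  a comment onset RANGE overrides the structured numeric age of onset;
R3  a comment onset PERIOD is ignored when a structured age exists;
R4  a comment onset STRING is ignored when a structured age exists;
R5  a deceased age with no structured onset yields an inferred onset
    RANGE bounded above by the deceased age;
R6  a specific comment family member overrides the structured family
    member, unless a conjunction ("and"/"also") precedes it, in which
    case both stay active;
R7  a nonspecific side-only comment ("father side") keeps the structured
    family member and records the side as a feature;
R8  a multiplicity-N family member expands into N instances.

All status changes are monotone (ACTIVE -> IGNORED only), which makes
reconciliation idempotent.
"""

from __future__ import annotations

import re

from .core import (
    CANCER_SITES,
    CONDITION_LABELS,
    Entity,
    EntityLabel,
    MarkedText,
    OnsetKind,
    OnsetValue,
    Side,
    Status,
)
from .lexicon import COLORECTAL_SYNDROMES, Lexicon
from .preprocess import strip_markers

__all__ = ["reconcile", "override_condition"]

_CONJUNCTION = re.compile(r"(?:\band\b|\balso\b|&|\+)[\s,]*$", re.IGNORECASE)

_ONSET_PRIORITY = {
    EntityLabel.ONSET_RANGE: 0,
    EntityLabel.ONSET_AGE: 1,
    EntityLabel.ONSET_PERIOD: 2,
    EntityLabel.ONSET_STRING: 3,
}


def _ignore(ent: Entity, reason: str) -> None:
    if ent.status is Status.ACTIVE:
        ent.status = Status.IGNORED
        ent.ignore_reason = reason


def reconcile(entities: list[Entity], marked: MarkedText, lexicon: Lexicon) -> list[Entity]:
    """Apply the eight reconciliation heuristics in order.

    Returns the entity list with statuses resolved, inferred onsets
    appended, and multiplicity mentions expanded into clone instances
    sharing an ``instance_group``.
    """
    comment = strip_markers(marked).lower()

    str_colon = [e for e in entities
                 if e.label is EntityLabel.COLON and e.is_structural]
    comment_syndromes = [e for e in entities
                        if e.label is EntityLabel.SYNDROME and not e.is_structural
                        and e.active and e.code in COLORECTAL_SYNDROMES]
    if comment_syndromes:  # R1
        for e in str_colon:
            _ignore(e, "R1: colorectal syndrome in comment")

    str_ages = [e for e in entities if e.label is EntityLabel.ONSET_AGE and e.is_structural]
    comment_ranges = [e for e in entities
                      if e.label is EntityLabel.ONSET_RANGE and not e.is_structural and e.active]
    if comment_ranges:  # R2
        for e in str_ages:
            _ignore(e, "R2: comment onset range overrides structured age")
    if str_ages:  # R3 / R4
        for e in entities:
            if e.is_structural:
                continue
            if e.label is EntityLabel.ONSET_PERIOD:
                _ignore(e, "R3: structured age present")
            elif e.label is EntityLabel.ONSET_STRING:
                _ignore(e, "R4: structured age present")

    # comment exact age corrects/duplicates a structured age: keep the comment
    comment_ages = [e for e in entities
                    if e.label is EntityLabel.ONSET_AGE and not e.is_structural and e.active]
    if comment_ages:
        for e in str_ages:
            _ignore(e, "comment age of onset preferred")

    # R5: infer an onset range ending at the deceased age
    deceased = [e for e in entities if e.label is EntityLabel.DECEASED_AGE and e.active]
    has_bounded_onset = any(
        e.active and e.label in (EntityLabel.ONSET_AGE, EntityLabel.ONSET_RANGE)
        for e in entities
    )
    already_inferred = any(
        e.label is EntityLabel.ONSET_RANGE and e.code == "INFERRED" for e in entities
    )
    if deceased and not str_ages and not has_bounded_onset and not already_inferred:
        d = deceased[0]
        entities.append(
            Entity(d.start, d.end, d.surface, EntityLabel.ONSET_RANGE,
                   code="INFERRED", segment_index=d.segment_index,
                   onset=OnsetValue(OnsetKind.RANGE, 0, d.onset.lower, raw=d.surface))
        )

    # R6 / R7: family-member resolution
    str_fms = [e for e in entities if e.label is EntityLabel.FAMILYMEMBER and e.is_structural]
    comment_fms = [e for e in entities
                   if e.label is EntityLabel.FAMILYMEMBER and not e.is_structural and e.active]
    overriding = [fm for fm in comment_fms
                  if not _CONJUNCTION.search(marked.text[: fm.start])]
    if overriding:  # R6
        for e in str_fms:
            _ignore(e, "R6: specific family member in comment")
    for phrase, side in lexicon.side_only_phrases.items():  # R7
        if phrase in comment:
            for e in str_fms:
                if e.active and e.side is Side.UNKNOWN:
                    e.side = side

    # keep at most one ACTIVE comment onset per segment (range beats age
    # beats period/string; leftmost breaks ties)
    by_segment: dict[int, list[Entity]] = {}
    for e in entities:
        if not e.is_structural and e.active and e.label in _ONSET_PRIORITY:
            by_segment.setdefault(e.segment_index, []).append(e)
    for seg_entities in by_segment.values():
        seg_entities.sort(key=lambda e: (_ONSET_PRIORITY[e.label], e.start))
        for e in seg_entities[1:]:
            _ignore(e, "secondary onset in segment")

    # R8: multiplicity expansion
    expanded: list[Entity] = []
    for e in entities:
        if e.label is EntityLabel.FAMILYMEMBER and e.active and e.multiplicity > 1:
            n = e.multiplicity
            e.multiplicity = 1
            e.instance_group = e.eid
            for _ in range(n - 1):
                expanded.append(e.clone(instance_group=e.eid))
    entities.extend(expanded)
    return entities


def override_condition(entities: list[Entity], marked: MarkedText, lexicon: Lexicon) -> list[Entity]:
    """Retire structured condition codes contradicted by the comment.

    Terms like "precancer" or "benign" in the narrative indicate the coded
    cancer does not describe a true malignancy, so the structured condition
    entity is ignored.  Terms inside ``{{ }}`` never fire: marked text is
    code, not narrative.
    """
    comment = strip_markers(marked).lower()
    if any(term in comment for term in lexicon.override_terms):
        for e in entities:
            if e.label in CONDITION_LABELS and e.is_structural:
                _ignore(e, "condition overridden by comment term")
    return entities
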