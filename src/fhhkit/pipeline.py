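"""End-to-end processing of single FHH entries.

``process_entry`` chains the four stages — field concatenation, entity
extraction, reconciliation, relation linking — and packages everything a
caller might want: the marked text, segments, entities (with statuses),
relations, orphan conditions, and normalized assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import Entity, FHHEntry, MarkedText, Relation, RelativeAssertion
from .extract import extract_entities
from .lexicon import Lexicon, default_lexicon
from .link import find_orphans, link_relations, to_assertions
from .preprocess import Segment, combine_fields
from .reconcile import override_condition, reconcile

__all__ = ["EntryAnnotation", "process_entry", "relation_signatures"]


@dataclass
class EntryAnnotation:
    """Complete pipeline output for one FHH entry."""

    entry: FHHEntry
    marked: MarkedText
    segments: list[Segment]
    entities: list[Entity]
    relations: list[Relation]
    assertions: list[RelativeAssertion]
    orphans: list[Entity] = field(default_factory=list)

    @property
    def active_entities(self) -> list[Entity]:
        return [e for e in self.entities if e.active]


def process_entry(entry: FHHEntry, lexicon: Optional[Lexicon] = None) -> EntryAnnotation:
    """Run concatenation, extraction, reconciliation and linking on one entry."""
    lexicon = lexicon or default_lexicon()
    marked = combine_fields(entry)
    entities, segments = extract_entities(marked, lexicon)
    override_condition(entities, marked, lexicon)
    reconcile(entities, marked, lexicon)
    relations = link_relations(entities, segments)
    assertions = to_assertions(entities, relations, entry, lexicon)
    orphans = find_orphans(entities, relations)
    return EntryAnnotation(entry, marked, segments, entities, relations, assertions, orphans)


def onset_repr(onset) -> Optional[str]:
    """Short canonical string for an onset value (AGE:52, RANGE:30-39, ...)."""
    if onset is None:
        return None
    if onset.kind.value == "AGE":
        return f"AGE:{onset.lower}"
    if onset.kind.value == "RANGE":
        return f"RANGE:{onset.lower}-{onset.upper}"
    return onset.kind.value


def relation_signatures(annotation: EntryAnnotation) -> list[tuple]:
    """Canonical, comparable relation tuples for evaluation.

    One tuple per emitted relation: (type, relative code, side, target
    value, uncertain), where the target value is the normalized condition
    for condition relations and the onset representation for FX_ONSET.
    Clone instances from multiplicity expansion each contribute their own
    tuples, matching how relations — not distinct relatives — are counted.
    """
    sigs: list[tuple] = []
    for r in annotation.relations:
        fm = r.source
        if r.type.value == "FX_ONSET":
            target_value = onset_repr(r.target.onset)
            uncertain = fm.uncertainty
        else:
            target_value = r.target.code or r.target.label.value
            uncertain = bool(r.target.uncertainty or fm.uncertainty)
        sigs.append((r.type.value, fm.code or fm.surface.strip().upper(),
                     fm.side.value, target_value, uncertain))
    return sigs
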