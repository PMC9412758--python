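"""Relation identification: link family members to conditions and onsets.

Within each sentence segment, every ACTIVE family member in scope is
linked to every ACTIVE condition entity in scope (FX_CANCER, FX_SYNDROME
or FX_GENE_MUT by condition type) and to the segment's ACTIVE onset
(FX_ONSET).  Structured-field entities are entry-global: a segment whose
narrative names no relative inherits the entry's structured relative, and
the structured condition and onset are visible from every segment.  One
relative with two cancers yields two FX_CANCER relations; one cancer
named for two relatives likewise.  Ignored entities never participate.

Relation counts — not distinct relative entities — are what the screening
criteria tally, so multiplicity-expanded clone instances each contribute a
relation; :func:`to_assertions` folds clones back into a single normalized
assertion with a count.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional

from .core import (
    CANCER_SITES,
    CONDITION_LABELS,
    ONSET_LABELS,
    Entity,
    EntityLabel,
    FHHEntry,
    Provenance,
    Relation,
    RelationType,
    RelativeAssertion,
)
from .lexicon import Lexicon
from .preprocess import Segment

__all__ = ["link_relations", "find_orphans", "to_assertions", "count_condition_relations"]

logger = logging.getLogger(__name__)

_CONDITION_RELATION = {
    EntityLabel.SYNDROME: RelationType.FX_SYNDROME,
    EntityLabel.GENE_MUT: RelationType.FX_GENE_MUT,
}


def _relation_type(label: EntityLabel) -> RelationType:
    if label in CANCER_SITES or label is EntityLabel.CANCER:
        return RelationType.FX_CANCER
    return _CONDITION_RELATION[label]


def link_relations(entities: list[Entity], segments: list[Segment]) -> list[Relation]:
    """Pair ACTIVE family members with conditions and onsets per segment."""
    structural_fms = [e for e in entities
                      if e.label is EntityLabel.FAMILYMEMBER and e.is_structural and e.active]
    structural_conditions = [e for e in entities
                             if e.label in CONDITION_LABELS and e.is_structural and e.active]
    structural_onsets = [e for e in entities
                         if e.label in ONSET_LABELS and e.is_structural and e.active]

    relations: list[Relation] = []
    seen: set[tuple[int, int]] = set()

    def emit(rtype: RelationType, fm: Entity, target: Entity) -> None:
        key = (fm.eid, target.eid)
        if key not in seen:
            seen.add(key)
            relations.append(Relation(rtype, fm, target))

    for seg in segments:
        comment_fms = [e for e in entities
                       if e.label is EntityLabel.FAMILYMEMBER and not e.is_structural
                       and e.active and e.segment_index == seg.index]
        scope_fms = comment_fms + structural_fms
        comment_conditions = [e for e in entities
                              if e.label in CONDITION_LABELS and not e.is_structural
                              and e.active and e.segment_index == seg.index]
        scope_conditions = comment_conditions + structural_conditions
        comment_onsets = [e for e in entities
                          if e.label in ONSET_LABELS and not e.is_structural
                          and e.active and e.segment_index == seg.index]
        scope_onset: Optional[Entity] = None
        if comment_onsets:
            scope_onset = comment_onsets[0]
        elif structural_onsets:
            scope_onset = structural_onsets[0]

        for fm in scope_fms:
            for cond in scope_conditions:
                emit(_relation_type(cond.label), fm, cond)
            if scope_onset is not None:
                emit(RelationType.FX_ONSET, fm, scope_onset)
    return relations


def find_orphans(entities: list[Entity], relations: list[Relation]) -> list[Entity]:
    """ACTIVE condition entities that no relation reached (logged, not raised)."""
    linked = {r.target.eid for r in relations}
    orphans = [e for e in entities
               if e.label in CONDITION_LABELS and e.active and e.eid not in linked]
    for e in orphans:
        logger.warning("orphan condition entity %r (%s) with no linked family member",
                       e.surface, e.label.value)
    return orphans


def to_assertions(entities: list[Entity], relations: list[Relation],
                  entry: FHHEntry, lexicon: Lexicon) -> list[RelativeAssertion]:
    """Normalize condition relations into per-relative assertions.

    Clone instances from multiplicity expansion collapse into a single
    assertion whose ``count`` is the number of instances; the onset linked
    to the same family member travels with each of its condition
    assertions.
    """
    onset_of: dict[int, Entity] = {}
    for r in relations:
        if r.type is RelationType.FX_ONSET:
            onset_of[r.source.eid] = r.target

    groups: dict[tuple, list[Relation]] = defaultdict(list)
    for r in relations:
        if r.type is RelationType.FX_ONSET:
            continue
        group_id = r.source.instance_group if r.source.instance_group is not None else r.source.eid
        groups[(group_id, r.target.eid)].append(r)

    assertions: list[RelativeAssertion] = []
    for (_, _), rels in sorted(groups.items(), key=lambda kv: kv[1][0].target.start):
        fm = rels[0].source
        target = rels[0].target
        onset_entity = onset_of.get(fm.eid)
        onset = onset_entity.onset if onset_entity is not None else None
        onset_source = None
        if onset_entity is not None:
            if onset_entity.code == "INFERRED":
                onset_source = "inferred"
            else:
                onset_source = "structured" if onset_entity.is_structural else "comment"
        assertions.append(
            RelativeAssertion(
                relative_code=fm.code or (fm.surface.strip().upper()),
                degree=lexicon.relative_degree(fm.code) if fm.code else None,
                side=fm.side,
                sex=fm.sex,
                condition=target.code or target.label.value,
                condition_kind=rels[0].type,
                onset=onset,
                uncertain=bool(target.uncertainty or fm.uncertainty),
                count=len(rels),
                provenance=Provenance(
                    entry_id=entry.entry_id,
                    relative_source="structured" if fm.is_structural else "comment",
                    condition_source="structured" if target.is_structural else "comment",
                    onset_source=onset_source,
                ),
            )
        )
    return assertions


def count_condition_relations(assertions: list[RelativeAssertion],
                              condition_set: set[str]) -> int:
    """Multiplicity-weighted number of relations whose condition is in the set."""
    return sum(a.count for a in assertions if a.condition in condition_set)
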