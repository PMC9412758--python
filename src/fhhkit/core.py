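"""Domain types for family health history (FHH) extraction and screening.

An FHH section entry in the EHR pairs coded structured fields (condition,
relative, age of onset) with a short free-text comment that supplements or
corrects them.  The types here model the raw entry, the marked concatenated
text the extractor runs over, typed entity spans with features, relations
linking family members to conditions and onsets, and the normalized
per-relative assertions consumed by the screening criteria engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "EntityLabel",
    "Status",
    "Side",
    "Sex",
    "OnsetKind",
    "RelationType",
    "Cohort",
    "Mode",
    "UncertaintyPolicy",
    "FHHEntry",
    "MarkedText",
    "OnsetValue",
    "Entity",
    "Relation",
    "RelativeAssertion",
    "PatientProfile",
    "EligibilityResult",
    "CANCER_SITES",
    "validate_entity",
]


class EntityLabel(str, Enum):
    FAMILYMEMBER = "FAMILYMEMBER"
    CANCER = "CANCER"  # generic, site unknown
    BLADDER = "BLADDER"
    BREAST = "BREAST"
    BRAIN = "BRAIN"
    COLON = "COLON"
    KIDNEY = "KIDNEY"
    OVARIAN = "OVARIAN"
    PANCREAS = "PANCREAS"
    PROSTATE = "PROSTATE"
    RECTAL = "RECTAL"
    STOMACH = "STOMACH"
    SMALL_INTESTINE = "SMALL_INTESTINE"
    URETERAL = "URETERAL"
    URETHRAL = "URETHRAL"
    ENDOMETRIAL = "ENDOMETRIAL"
    SYNDROME = "SYNDROME"
    GENE_MUT = "GENE_MUT"
    ONSET_AGE = "ONSET_AGE"
    ONSET_RANGE = "ONSET_RANGE"
    ONSET_PERIOD = "ONSET_PERIOD"
    ONSET_STRING = "ONSET_STRING"
    DECEASED_AGE = "DECEASED_AGE"


#: Cancer-site subtype labels (generic CANCER excluded).
CANCER_SITES = frozenset(
    {
        EntityLabel.BLADDER,
        EntityLabel.BREAST,
        EntityLabel.BRAIN,
        EntityLabel.COLON,
        EntityLabel.KIDNEY,
        EntityLabel.OVARIAN,
        EntityLabel.PANCREAS,
        EntityLabel.PROSTATE,
        EntityLabel.RECTAL,
        EntityLabel.STOMACH,
        EntityLabel.SMALL_INTESTINE,
        EntityLabel.URETERAL,
        EntityLabel.URETHRAL,
        EntityLabel.ENDOMETRIAL,
    }
)

CONDITION_LABELS = CANCER_SITES | {EntityLabel.CANCER, EntityLabel.SYNDROME, EntityLabel.GENE_MUT}
ONSET_LABELS = frozenset(
    {
        EntityLabel.ONSET_AGE,
        EntityLabel.ONSET_RANGE,
        EntityLabel.ONSET_PERIOD,
        EntityLabel.ONSET_STRING,
    }
)


class Status(str, Enum):
    ACTIVE = "ACTIVE"
    IGNORED = "IGNORED"


class Side(str, Enum):
    MATERNAL = "MATERNAL"
    PATERNAL = "PATERNAL"
    BOTH = "BOTH"
    UNKNOWN = "UNKNOWN"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class OnsetKind(str, Enum):
    AGE = "AGE"
    RANGE = "RANGE"
    PERIOD = "PERIOD"
    STRING = "STRING"


class RelationType(str, Enum):
    FX_CANCER = "FX_CANCER"
    FX_SYNDROME = "FX_SYNDROME"
    FX_GENE_MUT = "FX_GENE_MUT"
    FX_ONSET = "FX_ONSET"


class Cohort(str, Enum):
    BREAST_OVARIAN = "BREAST_OVARIAN"
    COLORECTAL = "COLORECTAL"


class Mode(str, Enum):
    STRUCTURED_ONLY = "STRUCTURED_ONLY"
    NLP_AUGMENTED = "NLP_AUGMENTED"


class UncertaintyPolicy(str, Enum):
    INCLUDE = "INCLUDE"
    EXCLUDE = "EXCLUDE"


@dataclass(frozen=True)
class FHHEntry:
    """One raw FHH assertion: structured fields plus a free-text comment."""

    patient_id: str
    entry_id: str
    condition_code: Optional[str] = None
    relative_code: Optional[str] = None
    onset_age: Optional[int] = None
    comment: str = ""
    entry_date: Optional[str] = None  # ISO calendar date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.onset_age is not None and not (0 <= self.onset_age <= 120):
            raise ValueError(f"onset_age {self.onset_age} outside [0, 120]")
        if not (self.condition_code or self.relative_code or self.comment):
            raise ValueError(
                "entry must carry at least one of condition_code/relative_code/comment"
            )


@dataclass(frozen=True)
class MarkedText:
    """Concatenated entry text with structured values wrapped in ``{{ }}``.

    ``source_spans`` maps each marked region (the full ``{{...}}`` span,
    half-open, 0-based) to the structured field it came from; ``comment_span``
    is the region holding the verbatim comment.
    """

    text: str
    source_spans: tuple[tuple[int, int, str], ...]
    comment_span: tuple[int, int]

    def field_of(self, start: int, end: int) -> Optional[str]:
        """Name of the structured field whose marked region contains [start, end)."""
        for s, e, name in self.source_spans:
            if s <= start and end <= e:
                return name
        return None

    def in_marked_region(self, start: int, end: int) -> bool:
        return self.field_of(start, end) is not None


@dataclass(frozen=True)
class OnsetValue:
    """Normalized age of onset.

    AGE is an exact year count; RANGE a bounded interval (e.g. a decade,
    "in his 30s" -> [30, 39]); PERIOD a calendar anchor ("in 1965") and
    STRING a non-numeric description, neither of which yields age bounds.
    """

    kind: OnsetKind
    lower: Optional[int] = None
    upper: Optional[int] = None
    raw: str = ""

    def __post_init__(self) -> None:
        if self.kind is OnsetKind.AGE:
            if self.lower is None or self.lower != self.upper:
                raise ValueError("AGE onset requires lower == upper")
        elif self.kind is OnsetKind.RANGE:
            if self.lower is None or self.upper is None or self.lower > self.upper:
                raise ValueError("RANGE onset requires lower <= upper")


_entity_ids = itertools.count(1)


@dataclass
class Entity:
    """A typed, featurized span over the marked concatenated text."""

    start: int
    end: int
    surface: str
    label: EntityLabel
    is_structural: bool = False
    uncertainty: bool = False
    status: Status = Status.ACTIVE
    code: Optional[str] = None  # normalized relative / condition value
    side: Side = Side.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    multiplicity: int = 1
    onset: Optional[OnsetValue] = None
    segment_index: int = 0
    eid: int = field(default_factory=lambda: next(_entity_ids))
    ignore_reason: Optional[str] = None
    instance_group: Optional[int] = None  # shared by multiplicity-expanded clones

    def clone(self, **changes) -> "Entity":
        new = replace(self, **changes)
        if "eid" not in changes:
            new.eid = next(_entity_ids)
        return new

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def active(self) -> bool:
        return self.status is Status.ACTIVE


def validate_entity(entity: Entity, text_length: Optional[int] = None) -> None:
    """Assert the structural invariants every pipeline-produced entity must hold."""
    if not 0 <= entity.start <= entity.end:
        raise ValueError(f"bad span {entity.span}")
    if text_length is not None and entity.end > text_length:
        raise ValueError(f"span {entity.span} beyond text length {text_length}")
    if entity.multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if entity.label is not EntityLabel.FAMILYMEMBER and (
        entity.side is not Side.UNKNOWN or entity.sex is not Sex.UNKNOWN
    ):
        raise ValueError("side/sex are only meaningful for FAMILYMEMBER entities")


@dataclass(frozen=True)
class Relation:
    """A typed link from an active family-member entity to a condition or onset."""

    type: RelationType
    source: Entity
    target: Entity

    def __post_init__(self) -> None:
        if self.source.label is not EntityLabel.FAMILYMEMBER:
            raise ValueError("relation source must be a FAMILYMEMBER entity")
        if not self.source.active:
            raise ValueError("relation source must be ACTIVE")
        ok = {
            RelationType.FX_CANCER: CANCER_SITES | {EntityLabel.CANCER},
            RelationType.FX_SYNDROME: {EntityLabel.SYNDROME},
            RelationType.FX_GENE_MUT: {EntityLabel.GENE_MUT},
            RelationType.FX_ONSET: ONSET_LABELS,
        }[self.type]
        if self.target.label not in ok:
            raise ValueError(f"target label {self.target.label} invalid for {self.type}")


@dataclass(frozen=True)
class Provenance:
    """Where each field of a normalized assertion came from."""

    entry_id: str
    relative_source: str = "structured"  # "structured" | "comment"
    condition_source: str = "structured"
    onset_source: Optional[str] = None
    note: Optional[str] = None


@dataclass(frozen=True)
class RelativeAssertion:
    """Post-reconciliation normalized row consumed by the criteria engine.

    ``degree`` is the degree of relationship to the patient (1 = parent/
    sibling/child, 2 = grandparent/aunt/uncle/niece/nephew/half-sibling/
    grandchild, 3 = great-grand generation and cousins) or None when the
    relative code is not in the configured degree table.
    """

    relative_code: str
    degree: Optional[int]
    side: Side
    sex: Sex
    condition: str  # normalized cancer site, syndrome name, or gene symbol
    condition_kind: RelationType
    onset: Optional[OnsetValue] = None
    uncertain: bool = False
    count: int = 1
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class PatientProfile:
    patient_id: str
    age: Optional[int] = None
    sex: Sex = Sex.UNKNOWN
    ashkenazi_jewish: Optional[bool] = None
    entries: list[FHHEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.patient_id != self.patient_id:
                raise ValueError(
                    f"entry {e.entry_id} belongs to {e.patient_id}, not {self.patient_id}"
                )


@dataclass(frozen=True)
class EligibilityResult:
    """Per-patient, per-cohort genetic-testing recommendation with provenance."""

    patient_id: str
    cohort: Cohort
    eligible: bool
    matched_criteria: tuple[str, ...]
    supporting: tuple[RelativeAssertion, ...]
    mode: Mode
    uncertainty_policy: UncertaintyPolicy

    def __post_init__(self) -> None:
        if self.eligible != bool(self.matched_criteria):
            raise ValueError("eligible must equal matched_criteria non-empty")
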