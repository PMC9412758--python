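"""NCCN family-history criteria engine for hereditary-cancer genetic testing.

Evaluates normalized per-relative assertions against the guideline
criteria for two cohorts.

Breast/ovarian cohort:
  BO1  first- or second-degree relative with breast cancer at age <= 45
  BO2  first- or second-degree relative with ovarian cancer
  BO3  first-degree relative with pancreatic cancer
  BO4  breast cancer in a male relative (any degree)
  BO5  >= 3 first-/second-degree relatives with breast or prostate cancer
       on the same side of the family (relation-counted)
  BO6  Ashkenazi Jewish ancestry and any breast or prostate cancer in any
       relative at any age
  BO7  BRCA1/2, CHEK2, ATM, PALB2, TP53, PTEN or CDH1, or Cowden /
       Li-Fraumeni syndrome, in any relative

Colorectal cohort:
  C1   MLH1, MSH2, PMS2, MSH6, EPCAM, MYH or MUTYH, or Lynch syndrome /
       FAP / APC / serrated polyposis / polyposis, in any relative
  C2   first-degree relative with colon cancer at age <= 50
  C3   first-degree relative with endometrial cancer at age <= 50
  C4   >= 3 first-/second-degree relatives on one side with Lynch
       syndrome or a cancer in the Lynch-spectrum site list

Counting for BO5/C4 uses relation counts (multiplicity-weighted), not
distinct persons; a relative whose side is BOTH (full siblings, the
patient's children and parents' shared descendants) counts toward each
side, and an UNKNOWN side counts toward neither by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .core import (
    Cohort,
    EligibilityResult,
    FHHEntry,
    Mode,
    OnsetKind,
    OnsetValue,
    PatientProfile,
    RelationType,
    RelativeAssertion,
    Sex,
    Side,
    UncertaintyPolicy,
)
from .lexicon import COLORECTAL_SYNDROMES, Lexicon, default_lexicon

__all__ = [
    "RangePolicy",
    "CriteriaConfig",
    "filter_relevant_entries",
    "degree_of",
    "side_of",
    "evaluate_breast_ovarian",
    "evaluate_colorectal",
    "screen_patient",
]

BO_GENES = frozenset({"BRCA1", "BRCA2", "CHEK2", "ATM", "PALB2", "TP53", "PTEN", "CDH1"})
BO_SYNDROMES = frozenset({"COWDEN", "LI_FRAUMENI"})
CRC_GENES = frozenset({"MLH1", "MSH2", "PMS2", "MSH6", "EPCAM", "MYH", "MUTYH", "APC"})
CRC_SYNDROMES = COLORECTAL_SYNDROMES  # LYNCH (incl. HNPCC), FAP, polyposis variants

#: Lynch-spectrum cancer sites counted by C4 (colon handled via colon_definition)
C4_SITES = frozenset(
    {"ENDOMETRIAL", "OVARIAN", "STOMACH", "SMALL_INTESTINE", "KIDNEY",
     "URETERAL", "BLADDER", "URETHRAL", "BRAIN", "PANCREAS"}
)


class RangePolicy(str, Enum):
    """How a RANGE onset meets an age threshold T.

    OPTIMISTIC: lower bound <= T (screening-oriented: "dx in 30s" meets
    a 45-year threshold).  STRICT: upper bound <= T.
    """

    OPTIMISTIC = "OPTIMISTIC"
    STRICT = "STRICT"


@dataclass
class CriteriaConfig:
    uncertainty_policy: UncertaintyPolicy = UncertaintyPolicy.INCLUDE
    range_threshold_policy: RangePolicy = RangePolicy.OPTIMISTIC
    #: extra relative_code -> degree entries overriding the lexicon table
    degree_overrides: dict[str, int] = field(default_factory=dict)
    #: count UNKNOWN-side assertions toward both sides in BO5/C4
    count_unknown_side: bool = False
    #: treat RECTAL as colon cancer for C2/C4
    colon_includes_rectal: bool = True
    #: comment-derived polyposis/syndrome assertions qualify for C1
    comment_syndromes_qualify: bool = True
    #: onset ranges inferred from a deceased age participate in thresholds
    inferred_range_participates: bool = True


def degree_of(relative_code: str, lexicon: Optional[Lexicon] = None,
              config: Optional[CriteriaConfig] = None) -> Optional[int]:
    """Degree of relationship for a normalized relative code (None if unknown)."""
    if config and relative_code in config.degree_overrides:
        return config.degree_overrides[relative_code]
    lexicon = lexicon or default_lexicon()
    return lexicon.relative_degree(relative_code)


def side_of(assertion: RelativeAssertion, config: Optional[CriteriaConfig] = None) -> Side:
    """Family side used for same-side counting (explicit feature wins)."""
    return assertion.side


def _onset_meets(assertion: RelativeAssertion, threshold: int, config: CriteriaConfig) -> bool:
    onset = assertion.onset
    if onset is None:
        return False
    if onset.kind is OnsetKind.AGE:
        return onset.lower <= threshold
    if onset.kind is OnsetKind.RANGE:
        if (not config.inferred_range_participates
                and assertion.provenance is not None
                and assertion.provenance.onset_source == "inferred"):
            return False
        bound = onset.lower if config.range_threshold_policy is RangePolicy.OPTIMISTIC else onset.upper
        return bound is not None and bound <= threshold
    return False  # PERIOD / STRING: no age computable


def _apply_uncertainty(assertions: list[RelativeAssertion],
                       config: CriteriaConfig) -> list[RelativeAssertion]:
    if config.uncertainty_policy is UncertaintyPolicy.EXCLUDE:
        return [a for a in assertions if not a.uncertain]
    return list(assertions)


def _same_side_count(assertions: list[RelativeAssertion], config: CriteriaConfig) -> int:
    """Largest per-side relation count among the given assertions."""
    totals = {Side.MATERNAL: 0, Side.PATERNAL: 0}
    for a in assertions:
        s = side_of(a, config)
        if s is Side.BOTH or (s is Side.UNKNOWN and config.count_unknown_side):
            totals[Side.MATERNAL] += a.count
            totals[Side.PATERNAL] += a.count
        elif s in totals:
            totals[s] += a.count
    return max(totals.values()) if totals else 0


def _colon_sites(config: CriteriaConfig) -> frozenset[str]:
    return frozenset({"COLON", "RECTAL"}) if config.colon_includes_rectal else frozenset({"COLON"})


def evaluate_breast_ovarian(profile: PatientProfile,
                            assertions: list[RelativeAssertion],
                            config: Optional[CriteriaConfig] = None,
                            lexicon: Optional[Lexicon] = None,
                            mode: Mode = Mode.NLP_AUGMENTED) -> EligibilityResult:
    """Evaluate the breast/ovarian-cohort criteria BO1-BO7."""
    config = config or CriteriaConfig()
    lexicon = lexicon or default_lexicon()
    kept = _apply_uncertainty(assertions, config)
    matched: list[str] = []
    supporting: list[RelativeAssertion] = []

    def deg(a: RelativeAssertion) -> Optional[int]:
        return a.degree if a.degree is not None else degree_of(a.relative_code, lexicon, config)

    bo1 = [a for a in kept if a.condition == "BREAST" and deg(a) in (1, 2)
           and _onset_meets(a, 45, config)]
    if bo1:
        matched.append("BO1")
        supporting.extend(bo1)
    bo2 = [a for a in kept if a.condition == "OVARIAN" and deg(a) in (1, 2)]
    if bo2:
        matched.append("BO2")
        supporting.extend(bo2)
    bo3 = [a for a in kept if a.condition == "PANCREAS" and deg(a) == 1]
    if bo3:
        matched.append("BO3")
        supporting.extend(bo3)
    bo4 = [a for a in kept if a.condition == "BREAST" and a.sex is Sex.MALE]
    if bo4:
        matched.append("BO4")
        supporting.extend(bo4)
    bo5_pool = [a for a in kept if a.condition in ("BREAST", "PROSTATE") and deg(a) in (1, 2)]
    if _same_side_count(bo5_pool, config) >= 3:
        matched.append("BO5")
        supporting.extend(bo5_pool)
    if profile.ashkenazi_jewish:
        bo6 = [a for a in kept if a.condition in ("BREAST", "PROSTATE")]
        if bo6:
            matched.append("BO6")
            supporting.extend(bo6)
    bo7 = [a for a in kept
           if (a.condition_kind is RelationType.FX_GENE_MUT and a.condition in BO_GENES)
           or (a.condition_kind is RelationType.FX_SYNDROME and a.condition in BO_SYNDROMES)]
    if bo7:
        matched.append("BO7")
        supporting.extend(bo7)

    return EligibilityResult(
        patient_id=profile.patient_id,
        cohort=Cohort.BREAST_OVARIAN,
        eligible=bool(matched),
        matched_criteria=tuple(matched),
        supporting=tuple(dict.fromkeys(supporting)),
        mode=mode,
        uncertainty_policy=config.uncertainty_policy,
    )


def evaluate_colorectal(profile: PatientProfile,
                        assertions: list[RelativeAssertion],
                        config: Optional[CriteriaConfig] = None,
                        lexicon: Optional[Lexicon] = None,
                        mode: Mode = Mode.NLP_AUGMENTED) -> EligibilityResult:
    """Evaluate the colorectal-cohort criteria C1-C4."""
    config = config or CriteriaConfig()
    lexicon = lexicon or default_lexicon()
    kept = _apply_uncertainty(assertions, config)
    matched: list[str] = []
    supporting: list[RelativeAssertion] = []
    colon = _colon_sites(config)

    def deg(a: RelativeAssertion) -> Optional[int]:
        return a.degree if a.degree is not None else degree_of(a.relative_code, lexicon, config)

    def syndrome_ok(a: RelativeAssertion) -> bool:
        if a.condition_kind is not RelationType.FX_SYNDROME:
            return False
        if not config.comment_syndromes_qualify and a.provenance is not None \
                and a.provenance.condition_source == "comment":
            return False
        return a.condition in CRC_SYNDROMES

    c1 = [a for a in kept
          if (a.condition_kind is RelationType.FX_GENE_MUT and a.condition in CRC_GENES)
          or syndrome_ok(a)]
    if c1:
        matched.append("C1")
        supporting.extend(c1)
    c2 = [a for a in kept if a.condition in colon and deg(a) == 1
          and _onset_meets(a, 50, config)]
    if c2:
        matched.append("C2")
        supporting.extend(c2)
    c3 = [a for a in kept if a.condition == "ENDOMETRIAL" and deg(a) == 1
          and _onset_meets(a, 50, config)]
    if c3:
        matched.append("C3")
        supporting.extend(c3)
    c4_sites = C4_SITES | colon
    c4_pool = [a for a in kept if deg(a) in (1, 2)
               and (a.condition in c4_sites
                    or (a.condition_kind is RelationType.FX_SYNDROME
                        and a.condition in ("LYNCH",)))]
    if _same_side_count(c4_pool, config) >= 3:
        matched.append("C4")
        supporting.extend(c4_pool)

    return EligibilityResult(
        patient_id=profile.patient_id,
        cohort=Cohort.COLORECTAL,
        eligible=bool(matched),
        matched_criteria=tuple(matched),
        supporting=tuple(dict.fromkeys(supporting)),
        mode=mode,
        uncertainty_policy=config.uncertainty_policy,
    )


def filter_relevant_entries(entries: list[FHHEntry],
                            lexicon: Optional[Lexicon] = None) -> list[FHHEntry]:
    """Keep entries usable for familial cancer-risk determination.

    An entry is relevant when its coded condition maps to a cancer,
    syndrome or gene, or its comment mentions any term from the condition
    lexicons; everything else (non-cancer family history) is dropped.
    """
    lexicon = lexicon or default_lexicon()
    from .core import EntityLabel

    condition_terms = [e.term for e in lexicon.entries
                       if e.label is not EntityLabel.FAMILYMEMBER]
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(t) for t in sorted(condition_terms, key=len, reverse=True))
        + r")\b",
        re.IGNORECASE,
    )
    kept = []
    for entry in entries:
        if entry.condition_code and lexicon.normalize_condition_code(entry.condition_code):
            kept.append(entry)
        elif entry.comment and pattern.search(entry.comment):
            kept.append(entry)
    return kept


def _structured_assertions(entry: FHHEntry, lexicon: Lexicon) -> list[RelativeAssertion]:
    """Assertions computable from the coded fields alone (comment ignored)."""
    condition = lexicon.normalize_condition_code(entry.condition_code) if entry.condition_code else None
    relative = lexicon.normalize_relative_code(entry.relative_code) if entry.relative_code else None
    if condition is None or relative is None:
        return []
    if condition in CRC_SYNDROMES or condition in BO_SYNDROMES:
        kind = RelationType.FX_SYNDROME
    elif condition in BO_GENES or condition in CRC_GENES:
        kind = RelationType.FX_GENE_MUT
    else:
        kind = RelationType.FX_CANCER
    entry_lex = lexicon.lookup(relative.lower().replace("_", " "))
    onset = None
    if entry.onset_age is not None:
        onset = OnsetValue(OnsetKind.AGE, entry.onset_age, entry.onset_age,
                           raw=str(entry.onset_age))
    from .core import Provenance

    return [
        RelativeAssertion(
            relative_code=relative,
            degree=lexicon.relative_degree(relative),
            side=entry_lex.side if entry_lex else Side.UNKNOWN,
            sex=entry_lex.sex if entry_lex else Sex.UNKNOWN,
            condition=condition,
            condition_kind=kind,
            onset=onset,
            uncertain=False,
            count=1,
            provenance=Provenance(entry_id=entry.entry_id,
                                  onset_source="structured" if onset else None),
        )
    ]


def screen_patient(profile: PatientProfile, mode: Mode,
                   config: Optional[CriteriaConfig] = None,
                   lexicon: Optional[Lexicon] = None) -> list[EligibilityResult]:
    """Screen one patient against both cohorts in the requested mode.

    STRUCTURED_ONLY builds assertions from the coded fields alone;
    NLP_AUGMENTED runs the full extraction pipeline over each entry first.
    """
    config = config or CriteriaConfig()
    lexicon = lexicon or default_lexicon()
    relevant = filter_relevant_entries(profile.entries, lexicon)
    assertions: list[RelativeAssertion] = []
    if mode is Mode.STRUCTURED_ONLY:
        for entry in relevant:
            assertions.extend(_structured_assertions(entry, lexicon))
    else:
        from .pipeline import process_entry

        for entry in relevant:
            assertions.extend(process_entry(entry, lexicon).assertions)
    return [
        evaluate_breast_ovarian(profile, assertions, config, lexicon, mode),
        evaluate_colorectal(profile, assertions, config, lexicon, mode),
    ]
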