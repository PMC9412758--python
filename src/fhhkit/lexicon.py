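"""Controlled vocabulary for FHH extraction.

A curated keyword dictionary maps surface terms (case-insensitive,
punctuation-tolerant) to entity labels and normalized values: cancer sites
and their synonyms, hereditary-cancer syndromes, pathogenic genes, family
members with sex/side/degree attributes, plus the cue lists used by the
context rules (uncertainty hedges, exclusion triggers, condition-override
terms).  The built-in tables are a reconstruction of a typical EHR code
list and are user-editable: every table can be replaced or extended from a
delimited file via :func:`load_lexicon_file`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core import EntityLabel, Sex, Side

__all__ = ["LexiconEntry", "Lexicon", "default_lexicon", "load_lexicon_file"]


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    label: EntityLabel
    normalized: str
    sex: Sex = Sex.UNKNOWN
    side: Side = Side.UNKNOWN
    degree: Optional[int] = None


# --- cancer sites -------------------------------------------------------
# term -> normalized site label name
_SITE_TERMS: dict[str, str] = {
    "bladder": "BLADDER",
    "breast": "BREAST",
    "brain": "BRAIN",
    "colon": "COLON",
    "colorectal": "COLON",
    "kidney": "KIDNEY",
    "renal": "KIDNEY",
    "ovarian": "OVARIAN",
    "ovary": "OVARIAN",
    "ovaries": "OVARIAN",
    "pancreas": "PANCREAS",
    "pancreatic": "PANCREAS",
    "prostate": "PROSTATE",
    "rectal": "RECTAL",
    "rectum": "RECTAL",
    "stomach": "STOMACH",
    "gastric": "STOMACH",
    "small intestine": "SMALL_INTESTINE",
    "small bowel": "SMALL_INTESTINE",
    "ureteral": "URETERAL",
    "ureter": "URETERAL",
    "urethral": "URETHRAL",
    "urethra": "URETHRAL",
    "endometrial": "ENDOMETRIAL",
    "endometrium": "ENDOMETRIAL",
    "uterine": "ENDOMETRIAL",
    "uterus": "ENDOMETRIAL",
}

# Aggregated types (gynecologic / gastrointestinal / genitourinary) are
# representable in the schema but deliberately absent from the extraction
# lexicon: they produce false positives against site-specific criteria.

_GENERIC_CANCER_TERMS = ("cancer", "ca", "carcinoma", "cancers")

_SYNDROME_TERMS: dict[str, str] = {
    "lynch syndrome": "LYNCH",
    "lynch": "LYNCH",
    "hnpcc": "LYNCH",
    "hereditary non-polyposis colorectal cancer": "LYNCH",
    "cowden syndrome": "COWDEN",
    "cowden": "COWDEN",
    "li-fraumeni syndrome": "LI_FRAUMENI",
    "li-fraumeni": "LI_FRAUMENI",
    "li fraumeni": "LI_FRAUMENI",
    "familial adenomatous polyposis": "FAP",
    "fap": "FAP",
    "serrated polyposis": "SERRATED_POLYPOSIS",
    "polyposis": "POLYPOSIS",
}

#: syndromes that qualify as colorectal-cancer syndromes (reconciliation R1,
#: criteria C1/C4)
COLORECTAL_SYNDROMES = frozenset({"LYNCH", "FAP", "SERRATED_POLYPOSIS", "POLYPOSIS"})

_GENE_TERMS: dict[str, str] = {
    "brca1": "BRCA1",
    "brca2": "BRCA2",
    "brca1/2": "BRCA1",
    "brca": "BRCA1",
    "chek2": "CHEK2",
    "atm": "ATM",
    "palb2": "PALB2",
    "tp53": "TP53",
    "p53": "TP53",
    "pten": "PTEN",
    "cdh1": "CDH1",
    "mlh1": "MLH1",
    "msh2": "MSH2",
    "pms2": "PMS2",
    "msh6": "MSH6",
    "epcam": "EPCAM",
    "myh": "MYH",
    "mutyh": "MUTYH",
    "apc": "APC",  # gene; also the FAP syndrome trigger in the colorectal criteria
}

# --- relatives ----------------------------------------------------------
# code -> (sex, inherent side, degree, synonyms)
_RELATIVES: dict[str, tuple[Sex, Side, int, tuple[str, ...]]] = {
    "MOTHER": (Sex.FEMALE, Side.MATERNAL, 1, ("mother", "mom", "mum")),
    "FATHER": (Sex.MALE, Side.PATERNAL, 1, ("father", "dad")),
    "SISTER": (Sex.FEMALE, Side.BOTH, 1, ("sister", "sisters", "sis")),
    "BROTHER": (Sex.MALE, Side.BOTH, 1, ("brother", "brothers")),
    "DAUGHTER": (Sex.FEMALE, Side.BOTH, 1, ("daughter", "daughters")),
    "SON": (Sex.MALE, Side.BOTH, 1, ("son", "sons")),
    "GRANDMOTHER": (Sex.FEMALE, Side.UNKNOWN, 2, ("grandmother", "grandma", "gma")),
    "GRANDFATHER": (Sex.MALE, Side.UNKNOWN, 2, ("grandfather", "grandpa", "gpa")),
    "MATERNAL_GRANDMOTHER": (Sex.FEMALE, Side.MATERNAL, 2, ("maternal grandmother", "maternal grandma", "mgm")),
    "MATERNAL_GRANDFATHER": (Sex.MALE, Side.MATERNAL, 2, ("maternal grandfather", "maternal grandpa", "mgf")),
    "PATERNAL_GRANDMOTHER": (Sex.FEMALE, Side.PATERNAL, 2, ("paternal grandmother", "paternal grandma", "pgm")),
    "PATERNAL_GRANDFATHER": (Sex.MALE, Side.PATERNAL, 2, ("paternal grandfather", "paternal grandpa", "pgf")),
    "AUNT": (Sex.FEMALE, Side.UNKNOWN, 2, ("aunt", "aunts", "aunty", "auntie")),
    "UNCLE": (Sex.MALE, Side.UNKNOWN, 2, ("uncle", "uncles")),
    "NIECE": (Sex.FEMALE, Side.UNKNOWN, 2, ("niece", "nieces")),
    "NEPHEW": (Sex.MALE, Side.UNKNOWN, 2, ("nephew", "nephews")),
    "HALF_SISTER": (Sex.FEMALE, Side.UNKNOWN, 2, ("half-sister", "half sister")),
    "HALF_BROTHER": (Sex.MALE, Side.UNKNOWN, 2, ("half-brother", "half brother")),
    "GRANDDAUGHTER": (Sex.FEMALE, Side.BOTH, 2, ("granddaughter",)),
    "GRANDSON": (Sex.MALE, Side.BOTH, 2, ("grandson",)),
    "GREAT_AUNT": (Sex.FEMALE, Side.UNKNOWN, 3, ("great-aunt", "great aunt", "greataunt")),
    "GREAT_UNCLE": (Sex.MALE, Side.UNKNOWN, 3, ("great-uncle", "great uncle")),
    "GREAT_GRANDMOTHER": (Sex.FEMALE, Side.UNKNOWN, 3, ("great-grandmother", "great grandmother")),
    "GREAT_GRANDFATHER": (Sex.MALE, Side.UNKNOWN, 3, ("great-grandfather", "great grandfather")),
    "COUSIN": (Sex.UNKNOWN, Side.UNKNOWN, 3, ("cousin", "cousins")),
}

#: structured condition codes -> (label name, normalized) — the editable
#: site-code table; generic "CANCER" maps to the generic label.
_CONDITION_CODES: dict[str, str] = {"CANCER": "CANCER"}
for _t, _site in _SITE_TERMS.items():
    _CONDITION_CODES[f"CANCER, {_site}"] = _site
_CONDITION_CODES.update({f"CANCER, {s}": s for s in set(_SITE_TERMS.values())})

_UNCERTAINTY_CUES = (
    "possible",
    "possibly",
    "probable",
    "probably",
    "maybe",
    "?",
    "unsure",
    "unknown type",
    "suspected",
)

_EXCLUSION_TRIGGERS = (
    "live with",
    "lives with",
    "lived with",
    "living with",
    "live w",
    "moved in with",
    "takes care of",
    "take care of",
    "cared for by",
)

_OVERRIDE_TERMS = ("precancer", "pre-cancer", "benign", "cyst", "no cancer", "not cancer")

_SIDE_ONLY_PHRASES: dict[str, Side] = {
    "father side": Side.PATERNAL,
    "father's side": Side.PATERNAL,
    "fathers side": Side.PATERNAL,
    "paternal side": Side.PATERNAL,
    "dad's side": Side.PATERNAL,
    "mother side": Side.MATERNAL,
    "mother's side": Side.MATERNAL,
    "mothers side": Side.MATERNAL,
    "maternal side": Side.MATERNAL,
    "mom's side": Side.MATERNAL,
}


@dataclass
class Lexicon:
    """All vocabulary tables the extractor and criteria engine consult."""

    entries: list[LexiconEntry]
    condition_codes: dict[str, str]
    uncertainty_cues: tuple[str, ...] = _UNCERTAINTY_CUES
    exclusion_triggers: tuple[str, ...] = _EXCLUSION_TRIGGERS
    override_terms: tuple[str, ...] = _OVERRIDE_TERMS
    side_only_phrases: dict[str, Side] = field(default_factory=lambda: dict(_SIDE_ONLY_PHRASES))
    typo_variants: dict[str, str] = field(default_factory=dict)  # optional curated typo list

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon has no entries")
        self._by_term = {e.term.lower(): e for e in self.entries}
        # longest-first term list for greedy longest matching
        self.sorted_terms = sorted(self._by_term, key=len, reverse=True)

    def lookup(self, term: str) -> Optional[LexiconEntry]:
        return self._by_term.get(term.lower())

    def relative_degree(self, code: str) -> Optional[int]:
        e = next(
            (x for x in self.entries if x.label is EntityLabel.FAMILYMEMBER and x.normalized == code),
            None,
        )
        return e.degree if e else None

    def normalize_condition_code(self, code: str) -> Optional[str]:
        """Map a structured condition code to a normalized condition, or None."""
        if code is None:
            return None
        key = re.sub(r"\s+", " ", code.strip().upper())
        if key in self.condition_codes:
            return self.condition_codes[key]
        # syndrome / gene codes occasionally appear in the coded field
        low = key.lower()
        if low in _SYNDROME_TERMS:
            return _SYNDROME_TERMS[low]
        if low in _GENE_TERMS:
            return _GENE_TERMS[low]
        return None

    def normalize_relative_code(self, code: str) -> Optional[str]:
        if code is None:
            return None
        key = code.strip().upper().replace(" ", "_").replace("-", "_")
        if key in _RELATIVES:
            return key
        e = self.lookup(code.strip().lower().replace("_", " "))
        if e is not None and e.label is EntityLabel.FAMILYMEMBER:
            return e.normalized
        return None


def default_lexicon() -> Lexicon:
    entries: list[LexiconEntry] = []
    for term, site in _SITE_TERMS.items():
        entries.append(LexiconEntry(term, EntityLabel[site], site))
        entries.append(LexiconEntry(f"{term} cancer", EntityLabel[site], site))
        entries.append(LexiconEntry(f"{term} ca", EntityLabel[site], site))
    for term in _GENERIC_CANCER_TERMS:
        entries.append(LexiconEntry(term, EntityLabel.CANCER, "CANCER"))
    for term, name in _SYNDROME_TERMS.items():
        entries.append(LexiconEntry(term, EntityLabel.SYNDROME, name))
    for term, gene in _GENE_TERMS.items():
        entries.append(LexiconEntry(term, EntityLabel.GENE_MUT, gene))
    for code, (sex, side, degree, synonyms) in _RELATIVES.items():
        for syn in synonyms:
            entries.append(
                LexiconEntry(syn, EntityLabel.FAMILYMEMBER, code, sex=sex, side=side, degree=degree)
            )
    return Lexicon(entries=entries, condition_codes=dict(_CONDITION_CODES))


def load_lexicon_file(path: str | Path, base: Optional[Lexicon] = None) -> Lexicon:
    """Extend (or build) a lexicon from a tab-delimited term table.

    Columns: term, label, normalized[, sex, side, degree].  Lines starting
    with ``#`` are comments.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"lexicon file missing or empty: {path}")
    entries = list(base.entries) if base else []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: expected at least 3 tab-separated columns")
        term, label, normalized = parts[:3]
        sex = Sex[parts[3]] if len(parts) > 3 and parts[3] else Sex.UNKNOWN
        side = Side[parts[4]] if len(parts) > 4 and parts[4] else Side.UNKNOWN
        degree = int(parts[5]) if len(parts) > 5 and parts[5] else None
        entries.append(
            LexiconEntry(term, EntityLabel[label], normalized, sex=sex, side=side, degree=degree)
        )
    codes = dict(base.condition_codes) if base else dict(_CONDITION_CODES)
    return Lexicon(entries=entries, condition_codes=codes)
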