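"""Synthetic FHH corpus generator with constructive gold annotations.

Real FHH-section data cannot be redistributed, so every pipeline stage is
exercised against generated corpora that emulate the observed entry
structure: coded condition / relative / age-of-onset fields supplemented
or corrected by short telegraphic comments.  Each entry is instantiated
from a phrase template tied to one comment phenomenon — site supplement,
onset supplement ("dx in her 30s"), relative correction ("great-aunt"
against a coded AUNT), conjunction ("and grandmother"), side-only
("father side"), multiplicity ("2× sisters"), uncertainty hedges,
condition overrides ("precancer"), deceased-age inference, calendar-year
red herrings, syndromes, gene variants, multi-cancer and multi-relative
phrasing, exclusion contexts, and irrelevant non-cancer noise.

The generator knows which relative/condition/onset it intended, so gold
relations and normalized assertions are built constructively alongside
each entry; gold eligibility follows by evaluating the criteria engine
over a patient's gold assertions.  Identical seeds give identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .core import (
    FHHEntry,
    Mode,
    OnsetKind,
    OnsetValue,
    PatientProfile,
    Provenance,
    RelationType,
    RelativeAssertion,
    Sex,
    Side,
)
from .criteria import CriteriaConfig, evaluate_breast_ovarian, evaluate_colorectal
from .lexicon import Lexicon, default_lexicon

__all__ = ["SimParams", "GoldEntry", "Corpus", "generate_corpus", "perturb_typos",
            "DEFAULT_PHENOMENON_WEIGHTS"]


#: default mix of comment phenomena; weights reflect that most entries are
#: fully structured or carry short supplements, while true conflicts
#: (relative corrections, overrides) are the minority
DEFAULT_PHENOMENON_WEIGHTS: dict[str, float] = {
    "structured_full": 0.26,
    "supplement_site": 0.14,
    "supplement_onset": 0.12,
    "onset_exact_comment": 0.05,
    "relative_correction": 0.06,
    "conjunction": 0.05,
    "side_only": 0.05,
    "multiplicity": 0.05,
    "uncertainty": 0.05,
    "condition_override": 0.04,
    "onset_period_ignored": 0.03,
    "deceased_age": 0.03,
    "syndrome_override": 0.03,
    "gene_mention": 0.02,
    "two_cancers": 0.02,
    "two_relatives": 0.02,
    "exclusion_context": 0.02,
    "irrelevant_noise": 0.06,
}


@dataclass
class SimParams:
    n_patients: int = 100
    mean_entries: float = 2.0
    max_entries: int = 5
    phenomenon_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOMENON_WEIGHTS))
    p_eligible_breast_ovarian: float = 0.15
    p_eligible_colorectal: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.max_entries < 1 or self.mean_entries < 1:
            raise ValueError("entries per patient must be >= 1")
        for p in (self.p_eligible_breast_ovarian, self.p_eligible_colorectal):
            if not 0 <= p <= 1:
                raise ValueError("eligible proportions must be in [0, 1]")
        bad = [k for k in self.phenomenon_weights if k not in DEFAULT_PHENOMENON_WEIGHTS]
        if bad:
            raise ValueError(f"unknown phenomena: {bad}")
        if any(w < 0 for w in self.phenomenon_weights.values()):
            raise ValueError("phenomenon weights must be non-negative")
        total = sum(self.phenomenon_weights.values())
        if total <= 0:
            raise ValueError("phenomenon weights sum to zero")
        cancer_weight = total - self.phenomenon_weights.get("irrelevant_noise", 0) \
            - self.phenomenon_weights.get("exclusion_context", 0)
        if cancer_weight <= 0 and (self.p_eligible_breast_ovarian > 0
                                   or self.p_eligible_colorectal > 0):
            raise ValueError("eligible patients requested but no cancer templates enabled")


@dataclass
class GoldEntry:
    """Reference annotation for one generated entry."""

    entry_id: str
    phenomenon: str
    relations: list[tuple]
    assertions: list[RelativeAssertion]
    planted: bool = False  # part of an eligibility-guaranteeing bundle
    ambiguous: bool = False


@dataclass
class Corpus:
    profiles: list[PatientProfile]
    gold: dict[str, GoldEntry]
    params: SimParams

    def entries(self) -> list[FHHEntry]:
        return [e for p in self.profiles for e in p.entries]

    def gold_assertions(self, patient_id: str) -> list[RelativeAssertion]:
        out: list[RelativeAssertion] = []
        profile = next(p for p in self.profiles if p.patient_id == patient_id)
        for e in profile.entries:
            out.extend(self.gold[e.entry_id].assertions)
        return out

    def gold_eligibility(self, config: Optional[CriteriaConfig] = None,
                         lexicon: Optional[Lexicon] = None) -> dict[str, dict[str, bool]]:
        """Reference eligibility per patient, from the gold assertions."""
        config = config or CriteriaConfig()
        lexicon = lexicon or default_lexicon()
        out = {}
        for p in self.profiles:
            assertions = self.gold_assertions(p.patient_id)
            bo = evaluate_breast_ovarian(p, assertions, config, lexicon, Mode.NLP_AUGMENTED)
            crc = evaluate_colorectal(p, assertions, config, lexicon, Mode.NLP_AUGMENTED)
            out[p.patient_id] = {"BREAST_OVARIAN": bo.eligible, "COLORECTAL": crc.eligible}
        return out


# --- template machinery --------------------------------------------------

_SITE_PHRASES = {
    "BREAST": ("Breast", "breast ca", "breast cancer"),
    "OVARIAN": ("ovarian", "ovarian cancer"),
    "COLON": ("colon ca", "colon cancer"),
    "STOMACH": ("stomach cancer", "gastric"),
    "KIDNEY": ("kidney cancer", "renal"),
    "PANCREAS": ("pancreatic", "pancreatic cancer"),
    "PROSTATE": ("prostate ca", "prostate cancer"),
    "BLADDER": ("bladder ca", "bladder cancer"),
    "BRAIN": ("brain cancer",),
}

#: filler sites/relatives chosen to exercise many labels
_FILLER_SITES = ("BREAST", "STOMACH", "KIDNEY", "BLADDER", "BRAIN", "PROSTATE", "COLON")
_FILLER_RELATIVES = ("AUNT", "UNCLE", "GRANDMOTHER", "GRANDFATHER", "COUSIN",
                      "NIECE", "NEPHEW", "MOTHER", "FATHER")


def _attrs(lexicon: Lexicon, code: str) -> tuple[Sex, Side, Optional[int]]:
    from .core import EntityLabel

    for e in lexicon.entries:
        if e.label is EntityLabel.FAMILYMEMBER and e.normalized == code:
            return e.sex, e.side, e.degree
    return Sex.UNKNOWN, Side.UNKNOWN, None


def _assertion(lexicon: Lexicon, entry_id: str, rel: str, condition: str,
               kind: RelationType, onset: Optional[OnsetValue] = None,
               uncertain: bool = False, count: int = 1,
               side: Optional[Side] = None,
               onset_source: Optional[str] = None) -> RelativeAssertion:
    sex, lex_side, degree = _attrs(lexicon, rel)
    return RelativeAssertion(
        relative_code=rel, degree=degree, side=side if side is not None else lex_side,
        sex=sex, condition=condition, condition_kind=kind, onset=onset,
        uncertain=uncertain, count=count,
        provenance=Provenance(entry_id=entry_id, onset_source=onset_source),
    )


def _sigs(assertions: list[RelativeAssertion],
          extra_onsets: Optional[list[tuple]] = None) -> list[tuple]:
    """Gold relation signatures in the pipeline's canonical tuple space."""
    from .pipeline import onset_repr

    sigs: list[tuple] = []
    seen_onset: set[tuple] = set()
    for a in assertions:
        for _ in range(a.count):
            sigs.append((a.condition_kind.value, a.relative_code, a.side.value,
                         a.condition, a.uncertain))
        if a.onset is not None:
            key = (a.relative_code, a.side.value, onset_repr(a.onset))
            if key not in seen_onset:
                seen_onset.add(key)
                sigs.extend(
                    [("FX_ONSET", a.relative_code, a.side.value, onset_repr(a.onset), False)]
                    * a.count
                )
    sigs.extend(extra_onsets or [])
    return sigs


@dataclass
class _Built:
    condition_code: Optional[str]
    relative_code: Optional[str]
    onset_age: Optional[int]
    comment: str
    assertions: list[RelativeAssertion]
    extra_onsets: list[tuple] = field(default_factory=list)


def _age(rng: np.random.Generator, lo: int = 35, hi: int = 75) -> int:
    return int(rng.integers(lo, hi + 1))


def _onset_age(a: int) -> OnsetValue:
    return OnsetValue(OnsetKind.AGE, a, a, raw=str(a))


def _build_template(name: str, rng: np.random.Generator, lexicon: Lexicon,
                    entry_id: str) -> _Built:
    pick = lambda seq: seq[int(rng.integers(0, len(seq)))]

    if name == "structured_full":
        site = pick(_FILLER_SITES)
        rel = pick(_FILLER_RELATIVES)
        a = _age(rng, 50, 80)
        return _Built(f"CANCER, {site}", rel, a, "",
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  _onset_age(a), onset_source="structured")])

    if name == "supplement_site":
        site = pick(_FILLER_SITES)
        rel = pick(_FILLER_RELATIVES)
        a = _age(rng, 50, 80) if rng.random() < 0.5 else None
        onset = _onset_age(a) if a is not None else None
        return _Built("CANCER", rel, a, pick(_SITE_PHRASES[site]),
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  onset, onset_source="structured" if a else None)])

    if name == "supplement_onset":
        site = pick(_FILLER_SITES)
        rel = pick(_FILLER_RELATIVES)
        decade = int(pick((30, 40, 50, 60, 70)))
        phrase, lo, hi = pick((
            (f"dx in her {decade}s", decade, decade + 9),
            (f"in his {decade}s", decade, decade + 9),
            (f"the late {decade}s", decade + 5, decade + 9),
            (f"early {decade}s", decade, decade + 4),
        ))
        onset = OnsetValue(OnsetKind.RANGE, lo, hi, raw=phrase)
        return _Built(f"CANCER, {site}", rel, None, phrase,
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  onset, onset_source="comment")])

    if name == "onset_exact_comment":
        site = pick(_FILLER_SITES)
        rel = pick(_FILLER_RELATIVES)
        a = _age(rng, 50, 80)
        comment = pick((f"dx at age of {a}", f"diagnosed at {a}", f"at age {a}"))
        return _Built(f"CANCER, {site}", rel, None, comment,
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  _onset_age(a), onset_source="comment")])

    if name == "relative_correction":
        site = pick(_FILLER_SITES)
        coded, phrase, actual = pick((
            ("AUNT", "Great-aunt", "GREAT_AUNT"),
            ("UNCLE", "Great-uncle", "GREAT_UNCLE"),
            ("GRANDMOTHER", "maternal grandmother", "MATERNAL_GRANDMOTHER"),
            ("GRANDFATHER", "paternal grandfather", "PATERNAL_GRANDFATHER"),
        ))
        a = _age(rng, 50, 80) if rng.random() < 0.5 else None
        return _Built(f"CANCER, {site}", coded, a, phrase,
                      [_assertion(lexicon, entry_id, actual, site, RelationType.FX_CANCER,
                                  _onset_age(a) if a else None,
                                  onset_source="structured" if a else None)])

    if name == "conjunction":
        site = pick(_FILLER_SITES)
        coded, phrase, extra = pick((
            ("MOTHER", "and grandmother", "GRANDMOTHER"),
            ("AUNT", "also uncle", "UNCLE"),
        ))
        a = _age(rng, 50, 80) if rng.random() < 0.5 else None
        onset = _onset_age(a) if a else None
        src = "structured" if a else None
        return _Built(f"CANCER, {site}", coded, a, phrase, [
            _assertion(lexicon, entry_id, extra, site, RelationType.FX_CANCER, onset,
                       onset_source=src),
            _assertion(lexicon, entry_id, coded, site, RelationType.FX_CANCER, onset,
                       onset_source=src),
        ])

    if name == "side_only":
        site = pick(_FILLER_SITES)
        rel = pick(("AUNT", "UNCLE", "GRANDMOTHER", "GRANDFATHER"))
        phrase, side = pick((
            ("Father side", Side.PATERNAL),
            ("father's side", Side.PATERNAL),
            ("mother's side", Side.MATERNAL),
            ("maternal side", Side.MATERNAL),
        ))
        a = _age(rng, 50, 80) if rng.random() < 0.5 else None
        return _Built(f"CANCER, {site}", rel, a, phrase,
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  _onset_age(a) if a else None, side=side,
                                  onset_source="structured" if a else None)])

    if name == "multiplicity":
        site = pick(_FILLER_SITES)
        n, phrase, rel = pick((
            (2, "2× sisters", "SISTER"),
            (2, "2 x aunts", "AUNT"),
            (3, "three aunts", "AUNT"),
            (2, "two uncles", "UNCLE"),
        ))
        return _Built(f"CANCER, {site}", None, None, phrase,
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  count=n)])

    if name == "uncertainty":
        rel = pick(_FILLER_RELATIVES)
        phrase, site = pick((
            ("possible, colon cancer", "COLON"),
            ("probably ovarian cancer", "OVARIAN"),
            ("suspected stomach cancer", "STOMACH"),
            ("breast cancer?", "BREAST"),
        ))
        return _Built("CANCER", rel, None, phrase,
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  uncertain=True)])

    if name == "condition_override":
        rel = pick(("MOTHER", "SISTER", "AUNT"))
        sex, side, _ = _attrs(lexicon, rel)
        variant = pick(("precancer, age 30", "benign cyst", "no cancer"))
        extra = []
        if variant == "precancer, age 30":
            extra = [("FX_ONSET", rel, side.value, "AGE:30", False)]
        return _Built("CANCER, BREAST", rel, None, variant, [], extra_onsets=extra)

    if name == "onset_period_ignored":
        site = pick(_FILLER_SITES)
        rel = pick(_FILLER_RELATIVES)
        a = _age(rng, 40, 80)
        year = int(rng.integers(1960, 2000))
        return _Built(f"CANCER, {site}", rel, a, f"In {year}",
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  _onset_age(a), onset_source="structured")])

    if name == "deceased_age":
        site = pick(_FILLER_SITES)
        rel = pick(_FILLER_RELATIVES)
        d = _age(rng, 50, 90)
        comment = pick((f"Deceased at age {d} years", f"died at {d}"))
        onset = OnsetValue(OnsetKind.RANGE, 0, d, raw=comment)
        return _Built(f"CANCER, {site}", rel, None, comment,
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  onset, onset_source="inferred")])

    if name == "syndrome_override":
        rel = pick(_FILLER_RELATIVES)
        return _Built("CANCER, COLON", rel, None, "Lynch syndrome",
                      [_assertion(lexicon, entry_id, rel, "LYNCH",
                                  RelationType.FX_SYNDROME)])

    if name == "gene_mention":
        rel = pick(("MOTHER", "SISTER", "FATHER", "AUNT"))
        gene = pick(("BRCA1", "BRCA2", "MLH1", "MSH2", "PALB2"))
        return _Built(None, rel, None, gene,
                      [_assertion(lexicon, entry_id, rel, gene,
                                  RelationType.FX_GENE_MUT)])

    if name == "two_cancers":
        rel = pick(("GRANDMOTHER", "AUNT", "MOTHER"))
        return _Built("CANCER", rel, None, "ovarian and stomach cancer", [
            _assertion(lexicon, entry_id, rel, "OVARIAN", RelationType.FX_CANCER),
            _assertion(lexicon, entry_id, rel, "STOMACH", RelationType.FX_CANCER),
        ])

    if name == "two_relatives":
        return _Built("CANCER", None, None, "breast cancer in mother and aunt", [
            _assertion(lexicon, entry_id, "MOTHER", "BREAST", RelationType.FX_CANCER),
            _assertion(lexicon, entry_id, "AUNT", "BREAST", RelationType.FX_CANCER),
        ])

    if name == "exclusion_context":
        site = pick(_FILLER_SITES)
        rel = pick(("MOTHER", "GRANDMOTHER"))
        a = _age(rng, 50, 80) if rng.random() < 0.5 else None
        return _Built(f"CANCER, {site}", rel, a, "lives with her daughter",
                      [_assertion(lexicon, entry_id, rel, site, RelationType.FX_CANCER,
                                  _onset_age(a) if a else None,
                                  onset_source="structured" if a else None)])

    if name == "irrelevant_noise":
        code, comment = pick((
            ("DIABETES", "insulin dependent"),
            ("HYPERTENSION", "controlled"),
            ("ASTHMA", ""),
        ))
        rel = pick(_FILLER_RELATIVES)
        return _Built(code, rel, None, comment, [])

    raise ValueError(f"unknown template {name!r}")


_ELIGIBLE_BO = ("bo_structured_breast", "bo_onset_range", "bo_ovarian")
_ELIGIBLE_CRC = ("crc_colon_young", "crc_lynch", "crc_gene")


def _build_eligible(kind: str, rng: np.random.Generator, lexicon: Lexicon,
                    entry_id: str) -> tuple[str, _Built]:
    """An entry guaranteed to satisfy at least one criterion of its cohort."""
    pick = lambda seq: seq[int(rng.integers(0, len(seq)))]
    if kind == "bo_structured_breast":  # BO1 via structured data alone
        rel = pick(("MOTHER", "SISTER", "AUNT"))
        a = _age(rng, 28, 44)
        return "structured_full", _Built(
            "CANCER, BREAST", rel, a, "",
            [_assertion(lexicon, entry_id, rel, "BREAST", RelationType.FX_CANCER,
                        _onset_age(a), onset_source="structured")])
    if kind == "bo_onset_range":  # BO1, onset only in the comment
        rel = pick(("SISTER", "MOTHER"))
        phrase = pick(("dx in her 30s", "early 40s"))
        lo = 30 if "30" in phrase else 40
        hi = lo + 9 if phrase.startswith("dx") else lo + 4
        onset = OnsetValue(OnsetKind.RANGE, lo, hi, raw=phrase)
        return "supplement_onset", _Built(
            "CANCER, BREAST", rel, None, phrase,
            [_assertion(lexicon, entry_id, rel, "BREAST", RelationType.FX_CANCER,
                        onset, onset_source="comment")])
    if kind == "bo_ovarian":  # BO2
        rel = pick(("MOTHER", "SISTER", "AUNT", "GRANDMOTHER"))
        a = _age(rng, 40, 70)
        return "structured_full", _Built(
            "CANCER, OVARIAN", rel, a, "",
            [_assertion(lexicon, entry_id, rel, "OVARIAN", RelationType.FX_CANCER,
                        _onset_age(a), onset_source="structured")])
    if kind == "crc_colon_young":  # C2
        rel = pick(("FATHER", "MOTHER"))
        a = _age(rng, 30, 50)
        return "structured_full", _Built(
            "CANCER, COLON", rel, a, "",
            [_assertion(lexicon, entry_id, rel, "COLON", RelationType.FX_CANCER,
                        _onset_age(a), onset_source="structured")])
    if kind == "crc_lynch":  # C1 via comment syndrome
        rel = pick(("MOTHER", "AUNT", "UNCLE"))
        return "syndrome_override", _Built(
            "CANCER, COLON", rel, None, "Lynch syndrome",
            [_assertion(lexicon, entry_id, rel, "LYNCH", RelationType.FX_SYNDROME)])
    if kind == "crc_gene":  # C1 via gene mention
        rel = pick(("MOTHER", "SISTER", "FATHER"))
        gene = pick(("MLH1", "MSH2", "MSH6"))
        return "gene_mention", _Built(
            None, rel, None, gene,
            [_assertion(lexicon, entry_id, rel, gene, RelationType.FX_GENE_MUT)])
    raise ValueError(kind)


def generate_corpus(params: SimParams, lexicon: Optional[Lexicon] = None) -> Corpus:
    """Generate a corpus of patient profiles with entry-level gold.

    Deterministic under a fixed seed.  Eligibility proportions are honored
    by planting, for the selected patients, one entry guaranteed to meet a
    criterion of the corresponding cohort; the remaining entries are drawn
    from the phenomenon-weight categorical distribution.
    """
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(params.seed)
    names = sorted(params.phenomenon_weights)
    weights = np.array([params.phenomenon_weights[n] for n in names], dtype=float)
    probs = weights / weights.sum()

    profiles: list[PatientProfile] = []
    gold: dict[str, GoldEntry] = {}
    counter = 0
    for i in range(params.n_patients):
        pid = f"P{i:05d}"
        n_entries = 1 + int(rng.poisson(max(params.mean_entries - 1, 0)))
        n_entries = min(n_entries, params.max_entries)
        planted: list[tuple[str, _Built, str]] = []
        if rng.random() < params.p_eligible_breast_ovarian:
            kind = _ELIGIBLE_BO[int(rng.integers(0, len(_ELIGIBLE_BO)))]
            counter += 1
            eid = f"E{counter:06d}"
            phen, built = _build_eligible(kind, rng, lexicon, eid)
            planted.append((phen, built, eid))
        if rng.random() < params.p_eligible_colorectal:
            kind = _ELIGIBLE_CRC[int(rng.integers(0, len(_ELIGIBLE_CRC)))]
            counter += 1
            eid = f"E{counter:06d}"
            phen, built = _build_eligible(kind, rng, lexicon, eid)
            planted.append((phen, built, eid))

        entries: list[FHHEntry] = []
        for phen, built, eid in planted:
            entries.append(FHHEntry(pid, eid, built.condition_code, built.relative_code,
                                    built.onset_age, built.comment))
            gold[eid] = GoldEntry(eid, phen, _sigs(built.assertions, built.extra_onsets),
                                  built.assertions, planted=True)
        for _ in range(max(n_entries - len(planted), 0)):
            name = names[int(rng.choice(len(names), p=probs))]
            counter += 1
            eid = f"E{counter:06d}"
            built = _build_template(name, rng, lexicon, eid)
            entries.append(FHHEntry(pid, eid, built.condition_code, built.relative_code,
                                    built.onset_age, built.comment))
            gold[eid] = GoldEntry(eid, name, _sigs(built.assertions, built.extra_onsets),
                                  built.assertions)
        profiles.append(PatientProfile(patient_id=pid, entries=entries))
    return Corpus(profiles=profiles, gold=gold, params=params)


def _typo(word: str) -> str:
    """Deterministic character-duplication edit ('bladder' -> 'bladdler')."""
    if len(word) < 4:
        return word
    return word[:-2] + word[1] + word[-2:]


def perturb_typos(corpus: Corpus, rate: float, seed: int = 0,
                  lexicon: Optional[Lexicon] = None) -> Corpus:
    """Apply character-level typos to comment condition terms.

    Each comment containing a recognizable condition term is perturbed
    with probability ``rate``.  Gold is left unchanged: typos model data-
    entry noise the extractor is expected to miss, so recall on a
    perturbed corpus can only stay equal or drop.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0:
        return corpus
    lexicon = lexicon or default_lexicon()
    from .core import EntityLabel

    terms = sorted(
        {e.term for e in lexicon.entries if e.label is not EntityLabel.FAMILYMEMBER
         and len(e.term) >= 4},
        key=len, reverse=True)
    rng = np.random.default_rng(seed)
    new_profiles = []
    for p in corpus.profiles:
        new_entries = []
        for e in p.entries:
            comment = e.comment
            if comment:
                low = comment.lower()
                hit = next((t for t in terms if t in low), None)
                if hit is not None and rng.random() < rate:
                    idx = low.find(hit)
                    original = comment[idx : idx + len(hit)]
                    comment = comment[:idx] + _typo(original) + comment[idx + len(hit):]
            new_entries.append(replace(e, comment=comment))
        new_profiles.append(PatientProfile(p.patient_id, p.age, p.sex,
                                           p.ashkenazi_jewish, new_entries))
    return Corpus(profiles=new_profiles, gold=corpus.gold, params=corpus.params)
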