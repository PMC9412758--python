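"""Criteria engine: degrees, sides, cohort rules, and oracle equivalence."""

import numpy as np
import pytest

from fhhkit import (
    CriteriaConfig,
    FHHEntry,
    Mode,
    OnsetKind,
    OnsetValue,
    PatientProfile,
    RangePolicy,
    RelationType,
    RelativeAssertion,
    Sex,
    Side,
    UncertaintyPolicy,
    degree_of,
    evaluate_breast_ovarian,
    evaluate_colorectal,
    filter_relevant_entries,
    screen_patient,
)


def A(rel, condition, kind=RelationType.FX_CANCER, onset=None, side=None,
      sex=None, degree=None, uncertain=False, count=1, lexicon=None):
    """Terse assertion builder with lexicon-derived defaults."""
    from fhhkit.simulate import _attrs
    from fhhkit import default_lexicon

    lx = lexicon or default_lexicon()
    lsex, lside, ldeg = _attrs(lx, rel)
    if isinstance(onset, int):
        onset = OnsetValue(OnsetKind.AGE, onset, onset)
    return RelativeAssertion(
        relative_code=rel, degree=degree if degree is not None else ldeg,
        side=side or lside, sex=sex or lsex, condition=condition,
        condition_kind=kind, onset=onset, uncertain=uncertain, count=count)


PROFILE = PatientProfile("P1")


@pytest.mark.parametrize("code,expected", [
    ("MOTHER", 1), ("SISTER", 1), ("SON", 1),
    ("AUNT", 2), ("GRANDFATHER", 2), ("HALF_SISTER", 2), ("NEPHEW", 2),
    ("GREAT_AUNT", 3), ("GREAT_GRANDMOTHER", 3), ("COUSIN", 3),
    ("STEPFATHER", None),
])
def test_degree_of(code, expected, lexicon):
    assert degree_of(code, lexicon) == expected


class TestBreastOvarian:
    def test_bo1_second_degree_breast_in_thirties(self):
        onset = OnsetValue(OnsetKind.RANGE, 30, 39)
        res = evaluate_breast_ovarian(PROFILE, [A("AUNT", "BREAST", onset=onset)])
        assert res.eligible and "BO1" in res.matched_criteria

    def test_no_assertions_not_eligible(self):
        res = evaluate_breast_ovarian(PROFILE, [])
        assert not res.eligible and res.matched_criteria == ()

    def test_bo5_only_for_three_same_side_relatives(self):
        assertions = [
            A("AUNT", "BREAST", onset=60, side=Side.PATERNAL),
            A("UNCLE", "PROSTATE", onset=65, side=Side.PATERNAL),
            A("GRANDMOTHER", "BREAST", onset=70, side=Side.PATERNAL),
        ]
        res = evaluate_breast_ovarian(PROFILE, assertions)
        assert res.matched_criteria == ("BO5",)

    def test_bo5_requires_same_side(self):
        assertions = [
            A("AUNT", "BREAST", onset=60, side=Side.PATERNAL),
            A("UNCLE", "PROSTATE", onset=65, side=Side.MATERNAL),
            A("GRANDMOTHER", "BREAST", onset=70, side=Side.UNKNOWN),
        ]
        assert not evaluate_breast_ovarian(PROFILE, assertions).eligible

    def test_bo4_male_breast_cancer_any_degree(self):
        res = evaluate_breast_ovarian(PROFILE, [A("GREAT_UNCLE", "BREAST")])
        assert res.matched_criteria == ("BO4",)

    def test_bo6_needs_ashkenazi_flag(self):
        aj = PatientProfile("P2", ashkenazi_jewish=True)
        assertions = [A("GREAT_AUNT", "BREAST", onset=80)]
        assert not evaluate_breast_ovarian(PROFILE, assertions).eligible
        res = evaluate_breast_ovarian(aj, assertions)
        assert res.matched_criteria == ("BO6",)

    def test_bo7_gene_and_syndrome_triggers(self):
        res = evaluate_breast_ovarian(
            PROFILE, [A("COUSIN", "BRCA2", kind=RelationType.FX_GENE_MUT)])
        assert res.matched_criteria == ("BO7",)
        res = evaluate_breast_ovarian(
            PROFILE, [A("COUSIN", "LI_FRAUMENI", kind=RelationType.FX_SYNDROME)])
        assert res.matched_criteria == ("BO7",)

    def test_range_policy_strict_vs_optimistic(self):
        onset = OnsetValue(OnsetKind.RANGE, 40, 49)
        a = [A("MOTHER", "BREAST", onset=onset)]
        opt = evaluate_breast_ovarian(PROFILE, a, CriteriaConfig())
        strict = evaluate_breast_ovarian(
            PROFILE, a, CriteriaConfig(range_threshold_policy=RangePolicy.STRICT))
        assert "BO1" in opt.matched_criteria
        assert "BO1" not in strict.matched_criteria

    def test_period_onset_never_meets_threshold(self):
        onset = OnsetValue(OnsetKind.PERIOD, raw="in 1965")
        assert not evaluate_breast_ovarian(PROFILE, [A("MOTHER", "BREAST", onset=onset)]).eligible


class TestColorectal:
    def test_c2_first_degree_colon_young(self):
        res = evaluate_colorectal(PROFILE, [A("FATHER", "COLON", onset=45)])
        assert res.matched_criteria == ("C2",)

    def test_c1_lynch_any_relative(self):
        res = evaluate_colorectal(
            PROFILE, [A("AUNT", "LYNCH", kind=RelationType.FX_SYNDROME)])
        assert "C1" in res.matched_criteria

    def test_endometrial_over_age_gate_not_eligible(self):
        res = evaluate_colorectal(PROFILE, [A("MOTHER", "ENDOMETRIAL", onset=55)])
        assert not res.eligible

    def test_rectal_counts_as_colon_by_default(self):
        a = [A("MOTHER", "RECTAL", onset=44)]
        assert evaluate_colorectal(PROFILE, a).eligible
        narrow = CriteriaConfig(colon_includes_rectal=False)
        assert not evaluate_colorectal(PROFILE, a, narrow).eligible

    def test_c4_three_lynch_spectrum_same_side(self):
        assertions = [
            A("AUNT", "STOMACH", side=Side.MATERNAL),
            A("GRANDMOTHER", "KIDNEY", side=Side.MATERNAL),
            A("MOTHER", "OVARIAN", onset=60),  # maternal by lineage
        ]
        res = evaluate_colorectal(PROFILE, assertions)
        assert "C4" in res.matched_criteria


class TestUncertaintyPolicy:
    def test_exclude_drops_uncertain_assertions(self):
        a = [A("FATHER", "COLON", onset=45, uncertain=True)]
        inc = evaluate_colorectal(PROFILE, a, CriteriaConfig())
        exc = evaluate_colorectal(
            PROFILE, a, CriteriaConfig(uncertainty_policy=UncertaintyPolicy.EXCLUDE))
        assert inc.eligible and not exc.eligible


class TestFilterRelevantEntries:
    def test_coded_cancer_kept(self):
        e = FHHEntry("P", "E", condition_code="CANCER")
        assert filter_relevant_entries([e]) == [e]

    def test_noncancer_code_dropped(self):
        e = FHHEntry("P", "E", condition_code="DIABETES", comment="insulin dependent")
        assert filter_relevant_entries([e]) == []

    def test_comment_lexicon_hit_kept(self):
        e = FHHEntry("P", "E", condition_code="OTHER", comment="Lynch syndrome")
        assert filter_relevant_entries([e]) == [e]


class TestScreenPatient:
    def test_worked_entry_not_eligible_either_mode(self, worked_entry):
        profile = PatientProfile("P1", entries=[worked_entry])
        for mode in (Mode.STRUCTURED_ONLY, Mode.NLP_AUGMENTED):
            for res in screen_patient(profile, mode):
                assert not res.eligible

    def test_comment_only_evidence_needs_nlp(self):
        entry = FHHEntry("P1", "E1", condition_code="CANCER", relative_code="AUNT",
                         comment="breast ca, dx in 30s")
        profile = PatientProfile("P1", entries=[entry])
        augmented = screen_patient(profile, Mode.NLP_AUGMENTED)
        structured = screen_patient(profile, Mode.STRUCTURED_ONLY)
        bo_aug = next(r for r in augmented if r.cohort.value == "BREAST_OVARIAN")
        bo_str = next(r for r in structured if r.cohort.value == "BREAST_OVARIAN")
        assert bo_aug.eligible and "BO1" in bo_aug.matched_criteria
        assert not bo_str.eligible


# --- exhaustive-criterion oracle ----------------------------------------

_C4_SITES = {"COLON", "RECTAL", "ENDOMETRIAL", "OVARIAN", "STOMACH", "SMALL_INTESTINE",
             "KIDNEY", "URETERAL", "BLADDER", "URETHRAL", "BRAIN", "PANCREAS"}


def _oracle(profile, assertions):
    """Direct per-criterion re-derivation by exhaustive iteration."""

    def meets(a, t):
        if a.onset is None:
            return False
        if a.onset.kind is OnsetKind.AGE:
            return a.onset.lower <= t
        if a.onset.kind is OnsetKind.RANGE:
            return a.onset.lower <= t
        return False

    def side_count(pool):
        best = 0
        for side in (Side.MATERNAL, Side.PATERNAL):
            n = 0
            for a in pool:
                if a.side is side or a.side is Side.BOTH:
                    n += a.count
            best = max(best, n)
        return best

    bo = set()
    if any(a.condition == "BREAST" and a.degree in (1, 2) and meets(a, 45) for a in assertions):
        bo.add("BO1")
    if any(a.condition == "OVARIAN" and a.degree in (1, 2) for a in assertions):
        bo.add("BO2")
    if any(a.condition == "PANCREAS" and a.degree == 1 for a in assertions):
        bo.add("BO3")
    if any(a.condition == "BREAST" and a.sex is Sex.MALE for a in assertions):
        bo.add("BO4")
    if side_count([a for a in assertions
                   if a.condition in ("BREAST", "PROSTATE") and a.degree in (1, 2)]) >= 3:
        bo.add("BO5")
    if profile.ashkenazi_jewish and any(a.condition in ("BREAST", "PROSTATE")
                                        for a in assertions):
        bo.add("BO6")
    if any((a.condition_kind is RelationType.FX_GENE_MUT
            and a.condition in {"BRCA1", "BRCA2", "CHEK2", "ATM", "PALB2", "TP53",
                                "PTEN", "CDH1"})
           or (a.condition_kind is RelationType.FX_SYNDROME
               and a.condition in {"COWDEN", "LI_FRAUMENI"}) for a in assertions):
        bo.add("BO7")

    crc = set()
    if any((a.condition_kind is RelationType.FX_GENE_MUT
            and a.condition in {"MLH1", "MSH2", "PMS2", "MSH6", "EPCAM", "MYH",
                                "MUTYH", "APC"})
           or (a.condition_kind is RelationType.FX_SYNDROME
               and a.condition in {"LYNCH", "FAP", "SERRATED_POLYPOSIS", "POLYPOSIS"})
           for a in assertions):
        crc.add("C1")
    if any(a.condition in ("COLON", "RECTAL") and a.degree == 1 and meets(a, 50)
           for a in assertions):
        crc.add("C2")
    if any(a.condition == "ENDOMETRIAL" and a.degree == 1 and meets(a, 50)
           for a in assertions):
        crc.add("C3")
    if side_count([a for a in assertions if a.degree in (1, 2)
                   and (a.condition in _C4_SITES
                        or (a.condition_kind is RelationType.FX_SYNDROME
                            and a.condition == "LYNCH"))]) >= 3:
        crc.add("C4")
    return bo, crc


def _random_assertion(rng, lexicon):
    rels = ["MOTHER", "FATHER", "SISTER", "BROTHER", "AUNT", "UNCLE",
            "GRANDMOTHER", "GREAT_AUNT", "COUSIN", "NEPHEW"]
    conditions = [("BREAST", RelationType.FX_CANCER), ("OVARIAN", RelationType.FX_CANCER),
                  ("COLON", RelationType.FX_CANCER), ("PANCREAS", RelationType.FX_CANCER),
                  ("PROSTATE", RelationType.FX_CANCER), ("STOMACH", RelationType.FX_CANCER),
                  ("ENDOMETRIAL", RelationType.FX_CANCER), ("KIDNEY", RelationType.FX_CANCER),
                  ("LYNCH", RelationType.FX_SYNDROME), ("COWDEN", RelationType.FX_SYNDROME),
                  ("BRCA1", RelationType.FX_GENE_MUT), ("MLH1", RelationType.FX_GENE_MUT)]
    rel = rels[rng.integers(0, len(rels))]
    cond, kind = conditions[rng.integers(0, len(conditions))]
    onset = None
    u = rng.random()
    if u < 0.4:
        a = int(rng.integers(20, 90))
        onset = OnsetValue(OnsetKind.AGE, a, a)
    elif u < 0.6:
        d = int(rng.integers(2, 8)) * 10
        onset = OnsetValue(OnsetKind.RANGE, d, d + 9)
    side = [None, Side.MATERNAL, Side.PATERNAL, Side.UNKNOWN][rng.integers(0, 4)]
    return A(rel, cond, kind=kind, onset=onset, side=side,
             count=int(rng.integers(1, 4)), lexicon=lexicon)


def test_engine_matches_exhaustive_oracle(lexicon):
    rng = np.random.default_rng(101)
    config = CriteriaConfig()
    for trial in range(250):
        profile = PatientProfile(f"P{trial}", ashkenazi_jewish=bool(rng.random() < 0.2))
        assertions = [_random_assertion(rng, lexicon) for _ in range(rng.integers(0, 10))]
        bo = evaluate_breast_ovarian(profile, assertions, config, lexicon)
        crc = evaluate_colorectal(profile, assertions, config, lexicon)
        obo, ocrc = _oracle(profile, assertions)
        assert set(bo.matched_criteria) == obo
        assert set(crc.matched_criteria) == ocrc


def test_monotonicity_in_evidence(lexicon):
    rng = np.random.default_rng(77)
    for trial in range(120):
        profile = PatientProfile(f"P{trial}")
        base = [_random_assertion(rng, lexicon) for _ in range(rng.integers(0, 6))]
        extra = base + [_random_assertion(rng, lexicon)]
        for fn in (evaluate_breast_ovarian, evaluate_colorectal):
            before = set(fn(profile, base, lexicon=lexicon).matched_criteria)
            after = set(fn(profile, extra, lexicon=lexicon).matched_criteria)
            assert before <= after
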