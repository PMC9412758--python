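"""Entity extraction: lexicon matching, context rules, onset/multiplicity parsing."""

import pytest

from fhhkit import (
    EntityLabel,
    FHHEntry,
    OnsetKind,
    Sex,
    Side,
    Status,
    combine_fields,
    extract_entities,
    parse_multiplicity,
    parse_onset,
)
from fhhkit.core import validate_entity


def _extract(lexicon, **kwargs):
    entry = FHHEntry("P", "E", **kwargs)
    marked = combine_fields(entry)
    entities, _ = extract_entities(marked, lexicon)
    return marked, entities


@pytest.mark.parametrize(
    "text,kind,lower,upper",
    [
        ("52", OnsetKind.AGE, 52, 52),
        ("age 52", OnsetKind.AGE, 52, 52),
        ("in his 30s", OnsetKind.RANGE, 30, 39),
        ("the late 50s", OnsetKind.RANGE, 55, 59),
        ("early 40s", OnsetKind.RANGE, 40, 44),
        ("60s", OnsetKind.RANGE, 60, 69),
        ("in 1965", OnsetKind.PERIOD, None, None),
        ("postmenstruation", OnsetKind.STRING, None, None),
    ],
)
def test_parse_onset(text, kind, lower, upper):
    onset = parse_onset(text)
    assert onset.kind is kind
    assert onset.lower == lower and onset.upper == upper


@pytest.mark.parametrize(
    "text,n",
    [("2× sisters", 2), ("2 x sisters", 2), ("x2", 2), ("three aunts", 3),
     ("sister", 1), ("0 × brothers", 1)],
)
def test_parse_multiplicity(text, n):
    assert parse_multiplicity(text) == n


class TestLexiconMatching:
    def test_worked_example_entities(self, lexicon, worked_entry):
        marked = combine_fields(worked_entry)
        entities, _ = extract_entities(marked, lexicon)
        by_label = {(e.label, e.surface.lower()) for e in entities}
        assert (EntityLabel.BREAST, "breast") in by_label
        assert (EntityLabel.FAMILYMEMBER, "great-aunt") in by_label
        assert (EntityLabel.ONSET_AGE, "52") in by_label
        assert (EntityLabel.FAMILYMEMBER, "aunt") in by_label  # structural {{AUNT}}
        for e in entities:
            validate_entity(e, text_length=len(marked.text))

    def test_syndrome_term(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER, COLON",
                               relative_code="AUNT", comment="Lynch syndrome")
        syn = [e for e in entities if e.label is EntityLabel.SYNDROME]
        assert len(syn) == 1 and syn[0].code == "LYNCH"

    def test_no_hits_gives_no_comment_entities(self, lexicon):
        _, entities = _extract(lexicon, condition_code="DIABETES",
                               comment="insulin dependent")
        assert [e for e in entities if not e.is_structural] == []

    def test_longest_match_wins(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER",
                               relative_code=None, comment="great aunt with colon cancer")
        fm = [e for e in entities if e.label is EntityLabel.FAMILYMEMBER]
        assert len(fm) == 1 and fm[0].code == "GREAT_AUNT"
        colon = [e for e in entities if e.label is EntityLabel.COLON]
        assert len(colon) == 1 and colon[0].surface == "colon cancer"

    def test_no_overlapping_active_same_label(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER",
                               relative_code="MOTHER",
                               comment="maternal grandmother breast cancer at 44")
        active = [e for e in entities if e.status is Status.ACTIVE]
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                if a.label is b.label:
                    assert a.end <= b.start or b.end <= a.start


class TestContextRules:
    def test_exclusion_context_ignores_family_member(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER, BREAST",
                               relative_code="MOTHER", comment="lives with her daughter")
        daughter = next(e for e in entities if e.code == "DAUGHTER")
        assert daughter.status is Status.IGNORED

    def test_uncertainty_cue_flags_condition(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER",
                               relative_code="FATHER", comment="possible, colon cancer")
        colon = next(e for e in entities if e.label is EntityLabel.COLON)
        assert colon.uncertainty

    def test_structural_flag_on_marked_values(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER", relative_code="AUNT",
                               comment="breast")
        aunt = next(e for e in entities if e.code == "AUNT")
        assert aunt.is_structural


class TestClassification:
    def test_side_cue_prefix(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER, BREAST",
                               relative_code=None, comment="paternal aunt")
        aunt = next(e for e in entities if e.label is EntityLabel.FAMILYMEMBER)
        assert aunt.side is Side.PATERNAL and aunt.code == "AUNT"

    def test_sex_from_lexicon(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER, COLON",
                               relative_code=None, comment="brother")
        fm = next(e for e in entities if e.label is EntityLabel.FAMILYMEMBER)
        assert fm.sex is Sex.MALE

    def test_generic_cancer_refined_by_comment_site(self, lexicon):
        _, entities = _extract(lexicon, condition_code="CANCER",
                               relative_code="AUNT", comment="Breast")
        generic = next(e for e in entities if e.label is EntityLabel.CANCER)
        site = next(e for e in entities if e.label is EntityLabel.BREAST)
        assert generic.status is Status.IGNORED and site.status is Status.ACTIVE


def test_extraction_is_deterministic(lexicon, worked_entry):
    marked = combine_fields(worked_entry)
    a, _ = extract_entities(marked, lexicon)
    b, _ = extract_entities(marked, lexicon)
    assert [(e.span, e.label, e.status) for e in a] == [(e.span, e.label, e.status) for e in b]
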