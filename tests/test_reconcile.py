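"""Reconciliation heuristics between structured and comment-derived entities."""

import pytest

from fhhkit import (
    EntityLabel,
    FHHEntry,
    OnsetKind,
    SimParams,
    Side,
    Status,
    generate_corpus,
    process_entry,
)


def _entry(**kwargs):
    return FHHEntry("P", "E", **kwargs)


def _active(ann, label):
    return [e for e in ann.entities if e.label is label and e.status is Status.ACTIVE]


def _ignored(ann, label):
    return [e for e in ann.entities if e.label is label and e.status is Status.IGNORED]


class TestHeuristics:
    def test_r1_syndrome_overrides_structured_colon(self):
        ann = process_entry(_entry(condition_code="CANCER, COLON",
                                   relative_code="AUNT", comment="Lynch syndrome"))
        assert _active(ann, EntityLabel.SYNDROME)
        assert _ignored(ann, EntityLabel.COLON)

    def test_r2_comment_range_overrides_structured_age(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="SISTER", onset_age=50,
                                   comment="The late 50s"))
        (rng,) = _active(ann, EntityLabel.ONSET_RANGE)
        assert (rng.onset.lower, rng.onset.upper) == (55, 59)
        assert all(e.is_structural for e in _ignored(ann, EntityLabel.ONSET_AGE))

    def test_r3_period_ignored_when_structured_age_exists(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="SISTER", onset_age=50,
                                   comment="In 1985"))
        (age,) = _active(ann, EntityLabel.ONSET_AGE)
        assert age.is_structural and age.onset.lower == 50
        assert _ignored(ann, EntityLabel.ONSET_PERIOD)

    def test_r4_string_ignored_when_structured_age_exists(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="SISTER", onset_age=50,
                                   comment="10 years ago"))
        (age,) = _active(ann, EntityLabel.ONSET_AGE)
        assert age.onset.lower == 50
        assert _ignored(ann, EntityLabel.ONSET_STRING)

    def test_r5_deceased_age_infers_onset_range(self):
        ann = process_entry(_entry(condition_code="CANCER, STOMACH",
                                   relative_code="GRANDMOTHER",
                                   comment="Deceased at age 60 years"))
        (rng,) = _active(ann, EntityLabel.ONSET_RANGE)
        assert rng.onset.kind is OnsetKind.RANGE
        assert (rng.onset.lower, rng.onset.upper) == (0, 60)

    def test_r6_specific_comment_relative_overrides_structured(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="AUNT", comment="Great-aunt"))
        fms = _active(ann, EntityLabel.FAMILYMEMBER)
        assert [f.code for f in fms] == ["GREAT_AUNT"]
        assert any(f.code == "AUNT" for f in _ignored(ann, EntityLabel.FAMILYMEMBER))

    def test_r6_conjunction_keeps_both_relatives(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="MOTHER", comment="And grandmother"))
        codes = {f.code for f in _active(ann, EntityLabel.FAMILYMEMBER)}
        assert codes == {"MOTHER", "GRANDMOTHER"}

    def test_r7_side_only_comment_adds_side_feature(self):
        ann = process_entry(_entry(condition_code="CANCER, OVARIAN",
                                   relative_code="AUNT", comment="Father side"))
        (aunt,) = _active(ann, EntityLabel.FAMILYMEMBER)
        assert aunt.code == "AUNT" and aunt.is_structural
        assert aunt.side is Side.PATERNAL

    def test_r8_multiplicity_expands_instances(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST", comment="2× sisters"))
        fms = _active(ann, EntityLabel.FAMILYMEMBER)
        assert len(fms) == 2
        assert all(f.code == "SISTER" and f.multiplicity == 1 for f in fms)
        assert len({f.instance_group for f in fms}) == 1


class TestConditionOverride:
    def test_precancer_overrides_structured_breast(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="MOTHER", comment="precancer, age 30"))
        assert _ignored(ann, EntityLabel.BREAST)
        assert not _active(ann, EntityLabel.BREAST)

    def test_no_override_term_leaves_entities_alone(self):
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="MOTHER", comment="doing well"))
        assert _active(ann, EntityLabel.BREAST)

    def test_override_scans_only_narrative_text(self):
        # the override scan is restricted to the comment region, so marked
        # structured values can never trigger it
        ann = process_entry(_entry(condition_code="CANCER, BREAST",
                                   relative_code="MOTHER", comment="dx at 40"))
        assert _active(ann, EntityLabel.BREAST)


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(SimParams(n_patients=120, seed=5))


class TestReconcileProperties:
    def test_idempotence(self, corpus, lexicon):
        from fhhkit.reconcile import reconcile

        for entry in corpus.entries():
            ann = process_entry(entry, lexicon)
            before = [(e.eid, e.status, e.side, e.multiplicity) for e in ann.entities]
            reconcile(ann.entities, ann.marked, lexicon)
            after = [(e.eid, e.status, e.side, e.multiplicity) for e in ann.entities]
            assert before == after

    def test_no_new_condition_entities(self, corpus, lexicon):
        from fhhkit import combine_fields, extract_entities
        from fhhkit.core import CONDITION_LABELS
        from fhhkit.reconcile import override_condition, reconcile

        for entry in corpus.entries():
            marked = combine_fields(entry)
            entities, _ = extract_entities(marked, lexicon)
            n_cond = sum(1 for e in entities if e.label in CONDITION_LABELS)
            override_condition(entities, marked, lexicon)
            reconcile(entities, marked, lexicon)
            assert sum(1 for e in entities if e.label in CONDITION_LABELS) == n_cond

    def test_at_most_one_active_comment_onset_per_segment(self, corpus):
        from fhhkit.core import ONSET_LABELS

        for entry in corpus.entries():
            ann = process_entry(entry)
            per_segment = {}
            for e in ann.entities:
                if e.label in ONSET_LABELS and e.status is Status.ACTIVE and not e.is_structural:
                    per_segment[e.segment_index] = per_segment.get(e.segment_index, 0) + 1
            assert all(v <= 1 for v in per_segment.values())
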