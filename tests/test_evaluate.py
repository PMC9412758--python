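"""Relation/eligibility scoring and bootstrap confidence intervals."""

import numpy as np
import pytest

from fhhkit import bootstrap_ci, compare_algorithms, score_relations
from fhhkit.evaluate import AlignmentError, Metrics, round2

SIG_A = ("FX_CANCER", "MOTHER", "MATERNAL", "BREAST", False)
SIG_B = ("FX_CANCER", "AUNT", "UNKNOWN", "COLON", False)
SIG_O = ("FX_ONSET", "MOTHER", "MATERNAL", "AGE:52", False)


class TestScoreRelations:
    def test_perfect_agreement(self):
        data = {"E1": [SIG_A, SIG_O], "E2": [SIG_B]}
        rep = score_relations(data, data)
        assert rep.micro.precision == rep.micro.recall == rep.micro.f1 == 1.0

    def test_disjoint_sets(self):
        rep = score_relations({"E1": [SIG_A]}, {"E1": [SIG_B]})
        assert rep.micro.precision == 0.0 and rep.micro.recall == 0.0

    def test_multiset_matching_within_entry(self):
        # two identical gold relations, one predicted: one TP one FN
        rep = score_relations({"E1": [SIG_A]}, {"E1": [SIG_A, SIG_A]})
        assert (rep.micro.tp, rep.micro.fp, rep.micro.fn) == (1, 0, 1)

    def test_zero_denominator_is_undefined_not_zero(self):
        rep = score_relations({"E1": []}, {"E1": []})
        assert rep.micro.precision is None and rep.micro.recall is None

    def test_alignment_error_on_id_mismatch(self):
        with pytest.raises(AlignmentError):
            score_relations({"E1": []}, {"E2": []})

    def test_micro_equals_summed_per_type_counts(self):
        rng = np.random.default_rng(4)
        sigs = [SIG_A, SIG_B, SIG_O, ("FX_SYNDROME", "AUNT", "UNKNOWN", "LYNCH", False)]
        pred, gold = {}, {}
        for i in range(40):
            pred[f"E{i}"] = [sigs[j] for j in rng.integers(0, 4, size=rng.integers(0, 5))]
            gold[f"E{i}"] = [sigs[j] for j in rng.integers(0, 4, size=rng.integers(0, 5))]
        rep = score_relations(pred, gold)
        assert rep.micro.tp == sum(m.tp for m in rep.per_type.values())
        assert rep.micro.fp == sum(m.fp for m in rep.per_type.values())
        assert rep.micro.fn == sum(m.fn for m in rep.per_type.values())


class TestMetricArithmetic:
    def test_confusion_counts_reproduce_two_decimal_rates(self):
        m = Metrics(tp=489, fp=32, fn=31)
        assert round2(m.precision) == 0.94
        assert round2(m.recall) == 0.94
        assert round2(m.f1) == 0.94

    def test_micro_average_from_summed_counts(self):
        rows = [(489, 32, 31), (2, 1, 3), (2, 0, 0), (203, 10, 14)]
        micro = Metrics(*(sum(c) for c in zip(*rows)))
        assert round2(micro.precision) == 0.94
        assert round2(micro.recall) == 0.94
        assert round2(micro.f1) == 0.94


class TestBootstrap:
    def test_constant_corpus_gives_zero_width(self):
        counts = [(1, 0, 0)] * 30
        lo, hi = bootstrap_ci(counts, "precision", B=200, seed=1)
        assert lo == hi == 1.0

    def test_point_estimate_inside_interval(self):
        rng = np.random.default_rng(8)
        counts = [(int(rng.integers(0, 4)), int(rng.integers(0, 2)),
                   int(rng.integers(0, 2))) for _ in range(60)]
        m = Metrics(*(sum(c) for c in zip(*counts)))
        lo, hi = bootstrap_ci(counts, "f1", B=1000, seed=3)
        assert lo <= m.f1 <= hi

    def test_deterministic_under_seed(self):
        counts = [(2, 1, 0), (1, 0, 1), (3, 1, 1), (0, 1, 0), (2, 0, 0), (1, 1, 1)]
        assert bootstrap_ci(counts, "f1", B=300, seed=9) == \
               bootstrap_ci(counts, "f1", B=300, seed=9)

    def test_sparse_support_flagged_unavailable(self):
        counts = [(0, 0, 0)] * 50 + [(1, 0, 1)] * 2  # rare type: 2 entries with counts
        assert bootstrap_ci(counts, "recall", B=100, seed=0) is None

    def test_b_zero_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([(1, 0, 0)] * 10, "f1", B=0)

    def test_interval_monotone_in_coverage(self):
        rng = np.random.default_rng(2)
        counts = [(int(rng.integers(0, 4)), int(rng.integers(0, 2)),
                   int(rng.integers(0, 2))) for _ in range(50)]
        lo90, hi90 = bootstrap_ci(counts, "f1", B=500, level=0.90, seed=4)
        lo99, hi99 = bootstrap_ci(counts, "f1", B=500, level=0.99, seed=4)
        assert lo99 <= lo90 and hi90 <= hi99


class TestCompareAlgorithms:
    def test_both_modes_equal_gold(self):
        gold = {f"P{i}": i % 2 == 0 for i in range(20)}
        out = compare_algorithms(gold, gold, gold, B=100, seed=1)
        for mode in out.values():
            assert mode.metrics.precision == 1.0 and mode.metrics.recall == 1.0

    def test_structured_blind_to_comment_evidence(self):
        # all eligibility evidence lives in comments: structured recall 0
        gold = {f"P{i}": True for i in range(10)}
        structured = {f"P{i}": False for i in range(10)}
        out = compare_algorithms(structured, gold, gold, B=100, seed=1)
        assert out["STRUCTURED_ONLY"].metrics.recall == 0.0
        assert out["NLP_AUGMENTED"].metrics.recall == 1.0

    def test_patient_set_mismatch_raises(self):
        with pytest.raises(AlignmentError, match="P9"):
            compare_algorithms({"P1": True}, {"P1": True}, {"P1": True, "P9": False})
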