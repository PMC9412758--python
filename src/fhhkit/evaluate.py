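"""Relation-level and patient-level scoring with bootstrap intervals.

A true-positive relation requires the relation type, both linked entities
and all feature values to match the reference; precision, recall and F1
are computed per relation type and micro-averaged over summed confusion
counts.  Confidence intervals use the percentile bootstrap, resampling
FHH entries for relation metrics and patients for eligibility metrics.
Rare relation types whose support is too sparse get no interval, mirroring
how CIs for very rare syndrome/gene relations cannot be estimated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Metrics",
    "RelationScoreReport",
    "AlignmentError",
    "score_relations",
    "bootstrap_ci",
    "compare_algorithms",
    "round2",
]


class AlignmentError(ValueError):
    """Prediction/reference sets cover different ids."""


def round2(x: Optional[float]) -> Optional[float]:
    """Round to 2 decimal places, half-up (reporting convention)."""
    if x is None:
        return None
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None if (p is None or r is None) else 0.0
        return 2 * p * r / (p + r)


def _metric_value(tp: int, fp: int, fn: int, metric: str) -> Optional[float]:
    m = Metrics(tp, fp, fn)
    return {"precision": m.precision, "recall": m.recall, "f1": m.f1}[metric]


@dataclass
class RelationScoreReport:
    per_type: dict[str, Metrics]
    micro: Metrics
    #: per-entry (tp, fp, fn) aggregated over all types, for bootstrapping
    per_entry_counts: list[tuple[int, int, int]] = field(default_factory=list)
    #: per-entry counts per type
    per_entry_by_type: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def table(self) -> str:
        """Human-readable metric table (counts plus 2-d.p. rates)."""
        rows = [f"{'Relation type':<14} {'TP':>5} {'FP':>5} {'FN':>5} "
                f"{'Precision':>9} {'Recall':>7} {'F1':>6}"]

        def fmt(v: Optional[float]) -> str:
            return "N/A" if v is None else f"{round2(v):.2f}"

        for name, m in list(self.per_type.items()) + [("micro", self.micro)]:
            rows.append(f"{name:<14} {m.tp:>5} {m.fp:>5} {m.fn:>5} "
                        f"{fmt(m.precision):>9} {fmt(m.recall):>7} {fmt(m.f1):>6}")
        return "\n".join(rows)


def _count_entry(pred: list[tuple], gold: list[tuple]) -> tuple[int, int, int]:
    """Multiset match of relation signatures within one entry."""
    pc, gc = Counter(pred), Counter(gold)
    tp = sum((pc & gc).values())
    return tp, sum(pc.values()) - tp, sum(gc.values()) - tp


def score_relations(predicted: dict[str, list[tuple]],
                    gold: dict[str, list[tuple]]) -> RelationScoreReport:
    """Score predicted vs reference relations, aligned by entry id.

    Signatures are compared as exact tuples whose first element is the
    relation type, so a true positive needs type, linked entities and all
    feature values to agree.  Ids present on only one side raise
    :class:`AlignmentError`.
    """
    if set(predicted) != set(gold):
        missing = set(predicted) ^ set(gold)
        raise AlignmentError(f"entry ids differ between prediction and reference: "
                             f"{sorted(missing)[:10]}")
    types = sorted({s[0] for sigs in list(gold.values()) + list(predicted.values())
                    for s in sigs})
    per_type: dict[str, Metrics] = {}
    per_entry_by_type: dict[str, list[tuple[int, int, int]]] = {t: [] for t in types}
    per_entry_counts: list[tuple[int, int, int]] = []
    totals = {t: [0, 0, 0] for t in types}
    for entry_id in sorted(gold):
        p, g = predicted[entry_id], gold[entry_id]
        etp = efp = efn = 0
        for t in types:
            tp, fp, fn = _count_entry([s for s in p if s[0] == t],
                                      [s for s in g if s[0] == t])
            totals[t][0] += tp
            totals[t][1] += fp
            totals[t][2] += fn
            per_entry_by_type[t].append((tp, fp, fn))
            etp, efp, efn = etp + tp, efp + fp, efn + fn
        per_entry_counts.append((etp, efp, efn))
    for t in types:
        per_type[t] = Metrics(*totals[t])
    micro = Metrics(
        sum(m.tp for m in per_type.values()),
        sum(m.fp for m in per_type.values()),
        sum(m.fn for m in per_type.values()),
    )
    return RelationScoreReport(per_type, micro, per_entry_counts, per_entry_by_type)


def bootstrap_ci(per_entry_counts: list[tuple[int, int, int]], metric: str = "f1",
                 B: int = 1000, level: float = 0.95, seed: int = 0,
                 min_support: int = 5) -> Optional[tuple[float, float]]:
    """Percentile bootstrap interval for a confusion-count metric.

    Resamples the per-unit (entry or patient) counts with replacement B
    times.  Returns None — interval unavailable — when fewer than
    ``min_support`` units carry any counts, as happens for very rare
    relation types.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    support = sum(1 for c in per_entry_counts if any(c))
    if support < min_support:
        return None
    counts = np.asarray(per_entry_counts, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = len(counts)
    stats = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        tp, fp, fn = counts[idx].sum(axis=0)
        v = _metric_value(int(tp), int(fp), int(fn), metric)
        if v is not None:
            stats.append(v)
    if not stats:
        return None
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return float(lo), float(hi)


@dataclass
class ModeComparison:
    """Eligibility metrics for one algorithm mode."""

    metrics: Metrics
    precision_ci: Optional[tuple[float, float]]
    recall_ci: Optional[tuple[float, float]]
    f1_ci: Optional[tuple[float, float]]
    per_patient_counts: list[tuple[int, int, int]]


def _eligibility_counts(pred: dict[str, bool], gold: dict[str, bool]) -> list[tuple[int, int, int]]:
    out = []
    for pid in sorted(gold):
        p, g = pred[pid], gold[pid]
        out.append((int(p and g), int(p and not g), int(g and not p)))
    return out


def compare_algorithms(results_structured: dict[str, bool],
                       results_augmented: dict[str, bool],
                       gold_eligibility: dict[str, bool],
                       B: int = 1000, level: float = 0.95,
                       seed: int = 0) -> dict[str, ModeComparison]:
    """Patient-level comparison of the two screening modes against reference.

    Inputs map patient id -> eligible flag (one cohort at a time, or
    either-cohort).  Returns per-mode precision/recall/F1 with bootstrap
    CIs over patients.
    """
    for name, d in (("structured", results_structured), ("augmented", results_augmented)):
        if set(d) != set(gold_eligibility):
            missing = sorted(set(d) ^ set(gold_eligibility))
            raise AlignmentError(f"{name} results and reference cover different "
                                 f"patients: {missing[:10]}")
    out: dict[str, ModeComparison] = {}
    for name, pred in (("STRUCTURED_ONLY", results_structured),
                       ("NLP_AUGMENTED", results_augmented)):
        counts = _eligibility_counts(pred, gold_eligibility)
        tp = sum(c[0] for c in counts)
        fp = sum(c[1] for c in counts)
        fn = sum(c[2] for c in counts)
        out[name] = ModeComparison(
            metrics=Metrics(tp, fp, fn),
            precision_ci=bootstrap_ci(counts, "precision", B, level, seed),
            recall_ci=bootstrap_ci(counts, "recall", B, level, seed),
            f1_ci=bootstrap_ci(counts, "f1", B, level, seed),
            per_patient_counts=counts,
        )
    return out
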