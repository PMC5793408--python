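"""Scoring somatic SNV predictions against spike-in truth sets.

Metrics follow benchmarking practice for whole-genome somatic calling:
precision (fraction of submitted calls that are true somatic SNVs), recall
(fraction of true somatic SNVs identified) and their harmonic mean, the
F1-score.  Specificity is deliberately not computed — on a whole genome the
true-negative count is astronomically large and would swamp it.

Zero conventions (documented because cohort statistics must stay total):
precision := 0 for an empty prediction set, and F1 := 0 whenever
precision + recall = 0.

Alongside the accuracy metrics, each prediction set is screened for germline
leakage: ``leak_count`` is the number of predicted keys that exactly match a
truth germline variant.  A key present in *both* truth sets scores as a true
positive but is flagged ambiguous; well-formed truth sets are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import LeakguardError
from .vcf_io import VariantSet

__all__ = ["ClassifiedCalls", "EvaluationResult", "classify_calls", "score"]


@dataclass(frozen=True)
class ClassifiedCalls:
    """Three-way partition of predicted keys, plus the ambiguous overlap."""

    true_positive: frozenset
    germline_leak: frozenset
    other_false_positive: frozenset
    ambiguous: frozenset  # keys in both truth sets; counted once, as TP


@dataclass(frozen=True)
class EvaluationResult:
    """All challenge metrics for one submission against one truth pair."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    leak_count: int
    leak_fraction_of_calls: float
    leak_fraction_of_fp: float

    @property
    def total_calls(self) -> int:
        return self.tp + self.fp

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "leak_count": self.leak_count,
            "leak_fraction_of_calls": self.leak_fraction_of_calls,
            "leak_fraction_of_fp": self.leak_fraction_of_fp,
        }


def classify_calls(
    predicted: VariantSet, truth_somatic: VariantSet, truth_germline: VariantSet
) -> ClassifiedCalls:
    """Partition predicted keys into true positives, germline leaks and other FPs."""
    pred, som, germ = predicted.keys, truth_somatic.keys, truth_germline.keys
    tp = pred & som
    leaks = (pred & germ) - som  # ambiguous keys count once, as TP
    other_fp = pred - som - germ
    return ClassifiedCalls(
        true_positive=frozenset(tp),
        germline_leak=frozenset(leaks),
        other_false_positive=frozenset(other_fp),
        ambiguous=frozenset(pred & som & germ),
    )


def score(
    predicted: VariantSet, truth_somatic: VariantSet, truth_germline: VariantSet
) -> EvaluationResult:
    """Precision/recall/F1 plus leakage quantities for one submission."""
    if not truth_somatic.keys:
        raise LeakguardError("truth somatic set must be non-empty for scoring")
    parts = classify_calls(predicted, truth_somatic, truth_germline)
    tp = len(parts.true_positive)
    total = len(predicted.keys)
    fp = total - tp
    fn = len(truth_somatic.keys) - tp
    precision = tp / total if total else 0.0
    recall = tp / len(truth_somatic.keys)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    leak_count = len(predicted.keys & truth_germline.keys)
    return EvaluationResult(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        leak_count=leak_count,
        leak_fraction_of_calls=leak_count / total if total else 0.0,
        leak_fraction_of_fp=leak_count / fp if fp else 0.0,
    )
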