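"""HCI performance accounting: single-trial analysis, sensitivity /
specificity / accuracy, Wolpaw-style bit transfer rate, and per-subject
report assembly.

The confusion-count semantics follow the study's literal event/nonevent
bookkeeping: a correctly classified event trial is a true positive, an
incorrectly classified event trial a false positive, a correctly
classified nonevent a true negative, and an incorrectly classified
nonevent a false negative.  A conventional one-vs-rest counting is
available behind ``conventional=True``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import TASKS, Task, is_event

__all__ = [
    "EvaluationError",
    "UndefinedMetricError",
    "ConfusionCounts",
    "BTRInputs",
    "SubjectReport",
    "single_trial_analysis",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "accuracy",
    "bit_transfer_rate",
    "subject_report",
]


class EvaluationError(ValueError):
    pass


class UndefinedMetricError(EvaluationError):
    """The metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class BTRInputs:
    """Inputs to the bit-transfer-rate formula."""

    n: int = 11            # number of selectable eye movements
    t_act: float = 2.0     # action period, seconds
    p_a: float = 1.0       # mean accuracy as a proportion

    def validate(self) -> None:
        if self.n < 2:
            raise EvaluationError("BTR needs n >= 2 commands")
        if self.t_act <= 0:
            raise EvaluationError("action period must be positive")
        if not (0 < self.p_a <= 1):
            raise EvaluationError("mean accuracy must be in (0, 1]")


def single_trial_analysis(predictions: Sequence[Task],
                          truths: Sequence[Task]) -> Dict[Task, float]:
    """Per-task accuracy in percent over that task's trials.

    Every task must appear the same number of times (10 in the study
    protocol), so the percentages land on multiples of 100/n_trials.
    """
    if len(predictions) != len(truths):
        raise EvaluationError("predictions/truths length mismatch")
    preds = [Task(p) for p in predictions]
    trues = [Task(t) for t in truths]
    counts = {task: 0 for task in TASKS}
    correct = {task: 0 for task in TASKS}
    for p, t in zip(preds, trues):
        counts[t] += 1
        if p == t:
            correct[t] += 1
    sizes = set(counts.values())
    if len(sizes) != 1 or 0 in sizes:
        raise EvaluationError(
            f"unbalanced trials per task: {sorted(sizes)}")
    n = sizes.pop()
    return {task: 100.0 * correct[task] / n for task in TASKS}


def confusion_counts(predictions: Sequence[Task], truths: Sequence[Task],
                     event_flags: Optional[Sequence[bool]] = None,
                     conventional: bool = False) -> ConfusionCounts:
    """Event/nonevent confusion bookkeeping.

    Default (study semantics): event trials count TP when correct and FP
    when not; nonevent trials count TN when correct and FN when not.
    ``conventional=True`` instead scores events-vs-nonevents one-vs-rest
    on the *predicted* event flag.
    """
    if len(predictions) != len(truths):
        raise EvaluationError("predictions/truths length mismatch")
    preds = [Task(p) for p in predictions]
    trues = [Task(t) for t in truths]
    if event_flags is None:
        event_flags = [is_event(t) for t in trues]
    elif len(event_flags) != len(trues):
        raise EvaluationError("event_flags length mismatch")
    tp = fp = tn = fn = 0
    for p, t, ev in zip(preds, trues, event_flags):
        if conventional:
            pred_ev = is_event(p)
            if ev and pred_ev:
                tp += 1
            elif ev and not pred_ev:
                fn += 1
            elif not ev and not pred_ev:
                tn += 1
            else:
                fp += 1
        else:
            if ev:
                tp += p == t
                fp += p != t
            else:
                tn += p == t
                fn += p != t
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: TP + FN = 0")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: TN + FP = 0")
    return c.TN / (c.TN + c.FP)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no trials")
    return (c.TP + c.TN) / c.total


def bit_transfer_rate(inp: BTRInputs) -> float:
    """Wolpaw information transfer rate in bits per minute:

        (60 / T_act) [log2 n + p log2 p + (1 - p) log2((1 - p)/(n - 1))]

    with the 0*log2(0) terms defined as 0, so p = 1 gives
    (60/T_act) log2 n and p = 1/n (chance) gives exactly 0.
    """
    inp.validate()
    n, t_act, p = inp.n, inp.t_act, inp.p_a
    if p == 1.0 / n:
        return 0.0
    bits = math.log2(n)
    if p > 0:
        bits += p * math.log2(p)
    if p < 1:
        bits += (1 - p) * math.log2((1 - p) / (n - 1))
    return (60.0 / t_act) * bits


# --------------------------------------------------------------------------
# Per-subject report
# --------------------------------------------------------------------------

@dataclass
class SubjectReport:
    """Max/min/mean/std accuracy over repeated runs plus the single-trial
    map, event/nonevent metrics and the bit transfer rate."""

    subject_id: str
    architecture: str
    max_accuracy: float
    min_accuracy: float
    mean_accuracy: float
    std_accuracy: float
    single_trial: Dict[str, float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    btr: float
    training_time: float = 0.0
    testing_time: float = 0.0
    extra: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def subject_report(subject_id: str, architecture: str,
                   run_accuracies: Sequence[float],
                   single_trial: Dict[Task, float],
                   confusion: Optional[ConfusionCounts] = None,
                   n_commands: int = 11, action_period: float = 2.0,
                   training_time: float = 0.0, testing_time: float = 0.0,
                   extra: Optional[Dict[str, float]] = None) -> SubjectReport:
    """Assemble the per-subject report.

    ``run_accuracies`` are percentages over repeated train/test runs;
    std is the sample standard deviation; BTR is computed from the mean
    accuracy as a proportion.
    """
    acc = np.asarray(list(run_accuracies), dtype=float)
    if acc.size < 2:
        raise EvaluationError("subject_report needs >= 2 runs")
    mean = float(acc.mean())
    btr = bit_transfer_rate(BTRInputs(n=n_commands, t_act=action_period,
                                      p_a=mean / 100.0))
    sens = spec = None
    if confusion is not None:
        sens = sensitivity(confusion)
        spec = specificity(confusion)
    return SubjectReport(
        subject_id=subject_id, architecture=architecture,
        max_accuracy=float(acc.max()), min_accuracy=float(acc.min()),
        mean_accuracy=mean, std_accuracy=float(acc.std(ddof=1)),
        single_trial={Task(k).value: float(v) for k, v in single_trial.items()},
        sensitivity=sens, specificity=spec, btr=btr,
        training_time=training_time, testing_time=testing_time,
        extra=dict(extra or {}))
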