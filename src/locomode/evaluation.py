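"""Performance metrics: per-class and macro F1, joint correctness, t-tests.

The class distribution of locomotion data is heavily imbalanced (transitions
are rare), so the F1-score — the harmonic mean of precision and recall —
is the reporting metric, macro-averaged over classes with nonzero support.

A composite prediction is *jointly* correct only when both the
activity (locomotion mode or transition) and the gait phase are right; a
truth without a phase (static modes, unphased windows) constrains only the
activity.  This makes the score an end-to-end measurement: a level-1
misroute sends the window to the wrong sub-models and is counted against
whatever they emit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .labels import CompositeLabel

logger = logging.getLogger(__name__)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and derived scores for a single class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def support(self) -> int:
        return self.tp + self.fn

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class EvaluationReport:
    """Per-class metrics, macro F1 scores and the confusion matrix.

    Two macro aggregations are reported.  ``mean_f1`` averages over the
    *composite* classes (every distinct activity-phase rendering): the
    strictest view, but at small sample sizes most transition-phase
    combinations are singletons and the average is dominated by them.
    ``mean_f1_levels`` averages over the activity classes and the
    gait-phase classes (the units the per-class confusion matrices are
    built from), with each window counted under the same joint-correctness
    rule; supports per class are larger, so this is the stable headline
    number.
    """

    per_class: dict[str, ClassMetrics]
    mean_f1: float
    per_activity: dict[str, ClassMetrics]
    per_phase: dict[str, ClassMetrics]
    mean_f1_levels: float
    classes: list[str]
    confusion: np.ndarray  # rows: truth, cols: prediction, order = classes
    n_windows: int

    def confusion_as_dict(self) -> dict[str, dict[str, int]]:
        return {
            t: {p: int(self.confusion[i, j]) for j, p in enumerate(self.classes)}
            for i, t in enumerate(self.classes)
        }


def joint_correct(pred: CompositeLabel, truth: CompositeLabel) -> bool:
    """True iff the activity matches and the phase matches.

    The phase comparison is vacuously true when the truth carries no phase
    (static modes have none; windows without phase coverage are unphased).
    """
    if pred.activity != truth.activity:
        return False
    if truth.phase is None:
        return True
    return pred.phase == truth.phase


def f1_report(
    preds: list[CompositeLabel],
    truths: list[CompositeLabel],
) -> EvaluationReport:
    """Score aligned prediction/truth lists of composite labels.

    Counting is one-vs-rest per rendered truth class under the joint
    correctness rule: a jointly correct prediction is a true positive of its
    truth's class; otherwise the truth's class gains a false negative and
    the *predicted* class a false positive.  ``mean_f1`` is the unweighted
    (macro) mean over classes with nonzero support; prediction-only classes
    are reported but excluded from the mean (and logged).
    """
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists must have equal length")
    if not truths:
        raise ValueError("cannot evaluate an empty prediction list")
    per_class: dict[str, ClassMetrics] = {}
    for label in list(map(str, truths)) + list(map(str, preds)):
        per_class.setdefault(label, ClassMetrics())
    classes = sorted(per_class)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    per_activity: dict[str, ClassMetrics] = {}
    per_phase: dict[str, ClassMetrics] = {}
    for pred, truth in zip(preds, truths):
        t, p = str(truth), str(pred)
        confusion[index[t], index[p]] += 1
        ok = joint_correct(pred, truth)
        if ok:
            per_class[t].tp += 1
        else:
            per_class[t].fn += 1
            per_class[p].fp += 1
        # level-wise counts under the same joint rule
        t_act, p_act = str(truth.activity), str(pred.activity)
        a = per_activity.setdefault(t_act, ClassMetrics())
        if ok:
            a.tp += 1
        else:
            a.fn += 1
            per_activity.setdefault(p_act, ClassMetrics()).fp += 1
        if truth.phase is not None:
            ph = per_phase.setdefault(str(truth.phase), ClassMetrics())
            if ok:
                ph.tp += 1
            else:
                ph.fn += 1
                if pred.phase is not None:
                    per_phase.setdefault(str(pred.phase), ClassMetrics()).fp += 1
    supported = [c for c in classes if per_class[c].support > 0]
    skipped = [c for c in classes if per_class[c].support == 0]
    if skipped:
        logger.info("classes with zero support excluded from macro F1: %s", skipped)
    mean_f1 = float(np.mean([per_class[c].f1 for c in supported]))
    level_scores = [
        m.f1
        for group in (per_activity, per_phase)
        for m in group.values()
        if m.support > 0
    ]
    mean_f1_levels = float(np.mean(level_scores)) if level_scores else mean_f1
    return EvaluationReport(
        per_class=per_class,
        mean_f1=mean_f1,
        per_activity=per_activity,
        per_phase=per_phase,
        mean_f1_levels=mean_f1_levels,
        classes=classes,
        confusion=confusion,
        n_windows=len(truths),
    )


def paired_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject (or per-seed) score pairs.

    Returns ``(t, p)`` with ``t = mean(d) / (sd(d) / sqrt(n))`` on the
    differences and p from Student's t with n-1 degrees of freedom.
    Zero-variance differences use the documented conventions: identical
    lists give ``(0.0, 1.0)``; a constant nonzero difference gives
    ``t = +/-inf`` with ``p = 0.0``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d score lists of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return t, p
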