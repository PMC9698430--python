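"""F1 scoring, the joint-correctness rule, and the paired t-test."""

import numpy as np
import pytest
from scipy import stats

from locomode.evaluation import ClassMetrics, f1_report, joint_correct, paired_t_test
from locomode.labels import CompositeLabel

P = CompositeLabel.parse


class TestJointCorrect:
    @pytest.mark.parametrize(
        "pred,truth,expected",
        [
            ("W to ST-W6", "W to ST-W6", True),
            ("W to ST-W6", "W to ST-W5", False),   # right activity, wrong phase
            ("W to W-W6", "W to ST-W6", False),    # wrong activity, right phase
            ("S to S", "S to S", True),            # no phase on either side
            ("W to W-W3", "W to W", True),         # truth without phase constrains activity only
        ],
    )
    def test_joint_rule(self, pred, truth, expected):
        assert joint_correct(P(pred), P(truth)) is expected


class TestF1Report:
    def test_perfect_predictions(self):
        labels = [P("W to W-W1"), P("S to S"), P("W to ST-W6")]
        report = f1_report(labels, labels)
        assert report.mean_f1 == 1.0
        assert report.mean_f1_levels == 1.0
        assert all(m.f1 == 1.0 for m in report.per_class.values())

    def test_levelwise_counts_match_bruteforce(self):
        rng = np.random.default_rng(5)
        pool = ["W to W-W1", "W to W-W2", "W to ST-W6", "S to S", "RA to RA-RA3"]
        truths = [P(pool[i]) for i in rng.integers(0, len(pool), 80)]
        preds = [P(pool[i]) for i in rng.integers(0, len(pool), 80)]
        report = f1_report(preds, truths)
        for act, m in report.per_activity.items():
            tp = sum(1 for p, t in zip(preds, truths)
                     if str(t.activity) == act and joint_correct(p, t))
            fn = sum(1 for p, t in zip(preds, truths)
                     if str(t.activity) == act and not joint_correct(p, t))
            fp = sum(1 for p, t in zip(preds, truths)
                     if str(p.activity) == act and not joint_correct(p, t))
            assert (m.tp, m.fn, m.fp) == (tp, fn, fp)
        for ph, m in report.per_phase.items():
            tp = sum(1 for p, t in zip(preds, truths)
                     if t.phase is not None and str(t.phase) == ph
                     and joint_correct(p, t))
            assert m.tp == tp
        scores = [m.f1 for g in (report.per_activity, report.per_phase)
                  for m in g.values() if m.support > 0]
        assert report.mean_f1_levels == pytest.approx(np.mean(scores))

    def test_hand_computed_counts(self):
        # one class with tp=8, fp=2, fn=4 against a filler class
        truths = [P("W to W")] * 12 + [P("S to S")] * 2
        preds = [P("W to W")] * 8 + [P("S to S")] * 4 + [P("W to W")] * 2
        report = f1_report(preds, truths)
        m = report.per_class["W to W"]
        assert (m.tp, m.fp, m.fn) == (8, 2, 4)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(0.7273, abs=1e-4)

    def test_all_wrong_single_class_f1_zero(self):
        truths = [P("W to W")] * 3
        preds = [P("S to S")] * 3
        report = f1_report(preds, truths)
        assert report.per_class["W to W"].f1 == 0.0
        assert report.mean_f1 == 0.0  # prediction-only class has no support

    def test_confusion_sums_to_n(self):
        rng = np.random.default_rng(0)
        pool = ["W to W-W1", "W to W-W2", "S to S", "W to ST-W6"]
        truths = [P(rng.choice(pool)) for _ in range(50)]
        preds = [P(rng.choice(pool)) for _ in range(50)]
        report = f1_report(preds, truths)
        assert report.confusion.sum() == report.n_windows == 50
        for i, cls in enumerate(report.classes):
            assert report.confusion[i].sum() == sum(1 for t in truths if str(t) == cls)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            f1_report([], [])

    def test_matches_bruteforce_oracle_on_random_lists(self):
        """One-vs-rest counting must agree with naive per-class loops."""
        rng = np.random.default_rng(42)
        pool = [
            "W to W-W1", "W to W-W2", "W to ST-W6", "S to S", "ST to ST",
            "RA to RA-RA3", "W to W",
        ]
        for _ in range(100):
            n = int(rng.integers(2, 40))
            truths = [P(pool[i]) for i in rng.integers(0, len(pool), n)]
            preds = [P(pool[i]) for i in rng.integers(0, len(pool), n)]
            report = f1_report(preds, truths)
            for cls in report.classes:
                tp = fp = fn = 0
                for p, t in zip(preds, truths):
                    ok = joint_correct(p, t)
                    if str(t) == cls:
                        if ok:
                            tp += 1
                        else:
                            fn += 1
                    if not ok and str(p) == cls:
                        fp += 1
                m = report.per_class[cls]
                assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
            supported = [c for c in report.classes if report.per_class[c].support]
            expect_mean = np.mean([report.per_class[c].f1 for c in supported])
            assert report.mean_f1 == pytest.approx(expect_mean)


class TestPairedTTest:
    def test_identical_lists_give_p_one(self):
        assert paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == (0.0, 1.0)

    def test_constant_nonzero_difference_gives_infinite_t(self):
        t, p = paired_t_test([1, 1, 1, 1], [0, 0, 0, 0])
        assert t == np.inf and p == 0.0
        t, p = paired_t_test([0, 0, 0, 0], [1, 1, 1, 1])
        assert t == -np.inf and p == 0.0

    def test_matches_direct_formula_and_scipy(self):
        d = np.array([0.1, 0.2, 0.15, 0.05, 0.1])
        a = 0.8 + d
        b = np.full(5, 0.8)
        t, p = paired_t_test(a, b)
        expect_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expect_t)
        sp = stats.ttest_rel(a, b)
        assert t == pytest.approx(sp.statistic)
        assert p == pytest.approx(sp.pvalue)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.5])


def test_class_metrics_zero_guards():
    m = ClassMetrics(tp=0, fp=0, fn=0)
    assert m.precision == m.recall == m.f1 == 0.0
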