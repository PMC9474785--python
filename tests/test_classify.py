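import dataclasses

import numpy as np
import pytest

import extravaquant as eq
from extravaquant.classify import EvaluationError, SeverityClass


class TestSeverityClasses:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, SeverityClass.NONE),
            (0.004, SeverityClass.NONE),
            (0.01, SeverityClass.MINOR),  # lower-inclusive boundary
            (0.049, SeverityClass.MINOR),
            (0.05, SeverityClass.MODERATE),
            (0.19, SeverityClass.MODERATE),
            (0.20, SeverityClass.SEVERE),
            (0.25, SeverityClass.SEVERE),
        ],
    )
    def test_boundaries(self, fraction, expected):
        assert eq.classify_severity(fraction) == expected

    def test_grid_matches_interval_table_oracle(self):
        def oracle(f):
            table = [(0.0, 0.01, 0), (0.01, 0.05, 1), (0.05, 0.20, 2), (0.20, np.inf, 3)]
            for lo, hi, c in table:
                if lo <= f < hi:
                    return c
        for f in np.linspace(0.0, 0.6, 10_000):
            assert int(eq.classify_severity(float(f))) == oracle(float(f))

    def test_nonfinite_rejected(self):
        with pytest.raises(EvaluationError):
            eq.classify_severity(float("nan"))

    def test_class_order(self):
        assert SeverityClass.NONE < SeverityClass.MINOR < SeverityClass.MODERATE < SeverityClass.SEVERE


class TestBinarize:
    def test_boundary_positive(self):
        assert eq.binarize(0.05) is True

    def test_just_below_negative(self):
        assert eq.binarize(0.049) is False

    def test_equivalence_with_class_grouping(self):
        rng = np.random.default_rng(0)
        for f in rng.uniform(0, 0.6, 500):
            via_fraction = eq.binarize(float(f))
            via_class = eq.classify_severity(float(f)) >= SeverityClass.MODERATE
            assert via_fraction == via_class


# printed binary confusion matrices for the three classifier variants
TABLE3 = {
    "qiba": (eq.ConfusionMatrix2x2(tp=4, tn=17, fp=2, fn=1),
             dict(sens=80.0, spec=89.5, acc=87.5, ppv=66.7, npv=94.4, mcc=0.65)),
    "optimal": (eq.ConfusionMatrix2x2(tp=4, tn=19, fp=0, fn=1),
                dict(sens=80.0, spec=100.0, acc=95.8, ppv=100.0, npv=95.0, mcc=0.87)),
    "radiologist": (eq.ConfusionMatrix2x2(tp=5, tn=6, fp=13, fn=0),
                    dict(sens=100.0, spec=31.6, acc=45.8, ppv=27.8, npv=100.0, mcc=0.30)),
}


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("name", list(TABLE3))
    def test_reference_confusion_matrices(self, name):
        cm, want = TABLE3[name]
        m = eq.diagnostic_metrics(cm)
        assert round(m.sensitivity, 1) == want["sens"]
        assert round(m.specificity, 1) == want["spec"]
        assert round(m.accuracy, 1) == want["acc"]
        assert round(m.ppv, 1) == want["ppv"]
        assert round(m.npv, 1) == want["npv"]
        assert round(m.mcc, 2) == want["mcc"]

    def test_perfect_classifier(self):
        m = eq.diagnostic_metrics(eq.ConfusionMatrix2x2(tp=3, tn=9, fp=0, fn=0))
        assert m.sensitivity == m.specificity == m.accuracy == m.ppv == m.npv == 100.0
        assert m.mcc == 1.0

    def test_zero_denominator_flagged(self):
        m = eq.diagnostic_metrics(eq.ConfusionMatrix2x2(tp=0, tn=5, fp=0, fn=0))
        assert "sensitivity" in m.undefined and np.isnan(m.sensitivity)
        assert m.mcc == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            eq.ConfusionMatrix2x2(tp=-1, tn=1, fp=0, fn=0)

    def test_metric_bounds_random(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 10, 4)
            if tp + tn + fp + fn == 0:
                continue
            m = eq.diagnostic_metrics(eq.ConfusionMatrix2x2(int(tp), int(tn), int(fp), int(fn)))
            for v in (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv):
                assert np.isnan(v) or 0.0 <= v <= 100.0
            assert -1.0 <= m.mcc <= 1.0


class TestMulticlassConfusion:
    def test_diagonal_when_perfect(self):
        classes = [SeverityClass(i % 4) for i in range(12)]
        cm = eq.multiclass_confusion(classes, classes)
        assert cm.trace() == 12
        assert cm.sum() == 12

    def test_reference_multiclass_layout(self):
        # predicted-class counts per truth column: truth marginals 13/6/3/2
        rows = [
            (0, 0, 9), (0, 1, 2),
            (1, 0, 4), (1, 1, 2), (1, 2, 1),
            (2, 1, 2), (2, 2, 1), (2, 3, 2),
            (3, 2, 1),
        ]
        pred, truth = [], []
        for p, t, n in rows:
            pred += [SeverityClass(p)] * n
            truth += [SeverityClass(t)] * n
        cm = eq.multiclass_confusion(pred, truth)
        assert cm.sum() == 24
        np.testing.assert_array_equal(cm.sum(axis=0), [13, 6, 3, 2])
        np.testing.assert_array_equal(
            cm, [[9, 2, 0, 0], [4, 2, 1, 0], [0, 2, 1, 2], [0, 0, 1, 0]]
        )

    def test_totals_invariant_under_permutation(self):
        rng = np.random.default_rng(2)
        pred = [SeverityClass(int(i)) for i in rng.integers(0, 4, 30)]
        truth = [SeverityClass(int(i)) for i in rng.integers(0, 4, 30)]
        cm = eq.multiclass_confusion(pred, truth)
        order = rng.permutation(30)
        cm2 = eq.multiclass_confusion([pred[i] for i in order], [truth[i] for i in order])
        np.testing.assert_array_equal(cm, cm2)

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError):
            eq.multiclass_confusion([SeverityClass.NONE], [])

    def test_binary_collapse_conserves_counts(self):
        rng = np.random.default_rng(3)
        frac_pred = rng.uniform(0, 0.4, 40)
        frac_truth = rng.uniform(0, 0.4, 40)
        pred = [eq.classify_severity(float(f)) for f in frac_pred]
        truth = [eq.classify_severity(float(f)) for f in frac_truth]
        cm4 = eq.multiclass_confusion(pred, truth)
        cm2 = eq.collapse_to_binary(cm4)
        direct = eq.ConfusionMatrix2x2.from_labels(
            np.array([eq.binarize(float(f)) for f in frac_pred]),
            np.array([eq.binarize(float(f)) for f in frac_truth]),
        )
        assert cm2 == direct
        assert cm2.n == 40


class TestOptimalThreshold:
    def test_clean_separation(self):
        res = eq.optimal_threshold([0.02, 0.03, 0.07, 0.08], [False, False, True, True])
        assert res.mcc == pytest.approx(1.0)
        assert res.lo == pytest.approx(0.03)
        assert res.hi == pytest.approx(0.07)

    def test_interleaved_matches_exhaustive_search(self):
        f = np.array([0.01, 0.03, 0.02, 0.06, 0.04, 0.09])
        y = np.array([False, True, False, True, False, True])
        res = eq.optimal_threshold(f, y)
        # exhaustive scan over a dense threshold grid
        grid = np.linspace(0.0, 0.12, 4001)
        def mcc_at(thr):
            cm = eq.ConfusionMatrix2x2.from_labels(f >= thr, y)
            return eq.mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn)
        best = max(mcc_at(t) for t in grid)
        assert res.mcc == pytest.approx(best)
        # every threshold strictly inside the returned interval is maximal
        interior = grid[(grid > res.lo) & (grid < res.hi)]
        assert interior.size > 0
        assert all(mcc_at(t) == pytest.approx(best) for t in interior)
        # and the interval is the widest contiguous maximal run
        winners = np.array([mcc_at(t) == pytest.approx(best) for t in grid])
        runs, cur = [], 0
        for w in winners:
            cur = cur + 1 if w else 0
            runs.append(cur)
        widest_run = max(runs) * (grid[1] - grid[0])
        assert res.hi - res.lo >= widest_run - 2 * (grid[1] - grid[0])

    def test_duplicates_do_not_move_bounds(self):
        f = [0.02, 0.03, 0.07, 0.08]
        y = [False, False, True, True]
        r1 = eq.optimal_threshold(f, y)
        r2 = eq.optimal_threshold(f + [0.03], y + [False])
        assert (r1.lo, r1.hi) == (r2.lo, r2.hi)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            eq.optimal_threshold([0.1, 0.2], [True, True])

    def test_max_mcc_at_least_qiba_threshold_mcc(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0, 0.3, 30)
        y = rng.random(30) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        res = eq.optimal_threshold(f, y)
        cm = eq.ConfusionMatrix2x2.from_labels(f >= 0.05, y)
        assert res.mcc >= eq.mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn) - 1e-12


class TestJackknife:
    def test_all_correct_gives_zero_se(self):
        truth = np.array([True, False, True, False, True])
        assert eq.jackknife_se(truth, truth) == 0.0

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(5)
        pred = rng.random(10) < 0.5
        truth = rng.random(10) < 0.5
        def mcc(p, t):
            cm = eq.ConfusionMatrix2x2.from_labels(p, t)
            return eq.mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn)
        reps = np.array([
            mcc(np.delete(pred, i), np.delete(truth, i)) for i in range(10)
        ])
        expected = np.sqrt(9 / 10 * np.sum((reps - reps.mean()) ** 2))
        assert eq.jackknife_se(pred, truth) == pytest.approx(expected, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        pred = rng.random(12) < 0.5
        truth = rng.random(12) < 0.5
        order = rng.permutation(12)
        assert eq.jackknife_se(pred, truth) == pytest.approx(
            eq.jackknife_se(pred[order], truth[order])
        )

    def test_too_small(self):
        with pytest.raises(EvaluationError):
            eq.jackknife_se([True, False], [True, False])


class TestCompareMcc:
    def test_equal_mccs_give_p_one(self):
        assert eq.compare_mcc(0.5, 0.1, 0.5, 0.2, 24) == 1.0

    def test_t_statistic_arithmetic(self):
        from scipy import stats
        p = eq.compare_mcc(0.87, 0.08, 0.30, 0.17, 24)
        t = (0.87 - 0.30) / np.hypot(0.08, 0.17)
        assert p == pytest.approx(2 * stats.t.sf(t, df=23))

    def test_monotone_in_difference(self):
        ps = [eq.compare_mcc(0.3 + d, 0.1, 0.3, 0.1, 24) for d in (0.1, 0.2, 0.4)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_zero_se(self):
        assert eq.compare_mcc(0.5, 0.0, 0.4, 0.0, 10) == 0.0
        assert eq.compare_mcc(0.5, 0.0, 0.5, 0.0, 10) == 1.0


class TestPipeline:
    def test_noiseless_cohort_complete(self, noiseless_cohort):
        _, pairs, studies, truths = noiseless_cohort
        res = eq.run_pipeline(pairs, studies=studies)
        assert res.n == 24
        assert res.confusion4.sum() == 24
        assert res.binary_cm.n == 24
        assert len(res.manifest["below_floor_subjects"]) + res.manifest["n_calibration_fit"] == 24

    def test_corrupt_subject_excluded(self, noiseless_cohort):
        _, pairs, studies, _ = noiseless_cohort
        pairs = list(pairs)
        t = np.arange(0.0, 120.0)  # far too short to extrapolate
        pairs[5] = dataclasses.replace(
            pairs[5], injection=eq.Tac(t, np.ones(120)), reference=eq.Tac(t, np.ones(120))
        )
        res = eq.run_pipeline(pairs, studies=studies)
        assert res.n == 23
        assert pairs[5].subject_id in res.excluded

    def test_deterministic(self, noisy_cohort):
        _, pairs, studies, _ = noisy_cohort
        r1 = eq.run_pipeline(pairs, studies=studies)
        r2 = eq.run_pipeline(pairs, studies=studies)
        assert [s.d_hat_raw for s in r1.subjects] == [s.d_hat_raw for s in r2.subjects]
        assert [s.predicted_class for s in r1.subjects] == [s.predicted_class for s in r2.subjects]
        assert r1.model.b0 == r2.model.b0
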