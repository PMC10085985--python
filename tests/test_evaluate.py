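"""Metric computations against independent oracles."""

import numpy as np
import pytest

from tearfilm import evaluate as ev


def random_table(rng, max_count=50, need_margins=False):
    while True:
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, max_count + 1, size=4))
        if tp + fp + fn + tn == 0:
            continue
        if need_margins and (tp + fp == 0 or tp + fn == 0 or tn + fp == 0 or tn + fn == 0):
            continue
        return ev.ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


class TestConfusion:
    def test_identity_and_inversion(self):
        truths = ["positive"] * 10 + ["negative"] * 10
        ct = ev.confusion(truths, truths)
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (10, 10, 0, 0)
        flipped = ["negative" if t == "positive" else "positive" for t in truths]
        ct2 = ev.confusion(flipped, truths)
        assert (ct2.tp, ct2.tn) == (0, 0)
        assert (ct2.fp, ct2.fn) == (10, 10)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            pred = rng.choice(["positive", "negative"], size=n)
            true = rng.choice(["positive", "negative"], size=n)
            ct = ev.confusion(pred, true, positive="positive")
            tp = fp = fn = tn = 0
            for p, t in zip(pred, true):
                if p == "positive" and t == "positive":
                    tp += 1
                elif p == "positive":
                    fp += 1
                elif t == "positive":
                    fn += 1
                else:
                    tn += 1
            assert (ct.tp, ct.fp, ct.fn, ct.tn) == (tp, fp, fn, tn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.confusion(["positive"], ["positive", "negative"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionTable(tp=-1, fp=0, fn=0, tn=1)


class TestAccuracyF1:
    def test_symmetric_table(self):
        acc, f1 = ev.accuracy_f1(ev.ConfusionTable(tp=40, fp=10, fn=10, tn=40), n_boot=200)
        assert acc.value == pytest.approx(0.8)
        assert f1.value == pytest.approx(0.8)
        assert acc.lo <= acc.value <= acc.hi

    def test_undefined_f1_flagged_not_zeroed(self):
        acc, f1 = ev.accuracy_f1(ev.ConfusionTable(tp=0, fp=0, fn=10, tn=90), n_boot=50)
        assert acc.value == pytest.approx(0.9)
        assert not f1.defined
        assert np.isnan(f1.value)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            ct = random_table(rng, need_margins=True)
            acc, f1 = ev.accuracy_f1(ct, n_boot=10)
            total = ct.tp + ct.fp + ct.fn + ct.tn
            assert abs(acc.value - (ct.tp + ct.tn) / total) < 1e-12
            prec = ct.tp / (ct.tp + ct.fp)
            rec = ct.tp / (ct.tp + ct.fn)
            expected_f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            assert abs(f1.value - expected_f1) < 1e-12

    def test_bootstrap_is_seeded(self):
        ct = ev.ConfusionTable(tp=30, fp=5, fn=7, tn=28)
        a = ev.accuracy_f1(ct, n_boot=100, seed=5)[1]
        b = ev.accuracy_f1(ct, n_boot=100, seed=5)[1]
        assert (a.lo, a.hi) == (b.lo, b.hi)


class TestRocAuc:
    def test_perfect_separation(self):
        conf = [0.9, 0.8, 0.7, 0.2, 0.1, 0.0]
        labels = [1, 1, 1, 0, 0, 0]
        auc, curve = ev.roc_auc(conf, labels, n_boot=50)
        assert auc.value == pytest.approx(1.0)
        assert {"threshold", "tpr", "fpr"} <= set(curve.columns)

    def test_chance_level_for_independent_scores(self):
        rng = np.random.default_rng(0)
        conf = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        auc, _ = ev.roc_auc(conf, labels, n_boot=10)
        assert auc.value == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_pair_counting(self):
        """For n <= 12 the rank AUC equals brute-force pair counting with
        half credit for ties."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            conf = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            auc, _ = ev.roc_auc(conf, labels, n_boot=2)
            pairs = 0.0
            npairs = 0
            for cp in conf[labels == 1]:
                for cn in conf[labels == 0]:
                    npairs += 1
                    pairs += 1.0 if cp > cn else (0.5 if cp == cn else 0.0)
            assert abs(auc.value - pairs / npairs) < 1e-12

    def test_rank_auc_equals_trapezoid_sweep(self):
        rng = np.random.default_rng(4)
        conf = np.round(rng.random(200), 2)
        labels = (rng.random(200) < 0.4).astype(int)
        auc, curve = ev.roc_auc(conf, labels, n_boot=2)
        trapezoid = np.trapezoid(curve["tpr"], curve["fpr"])
        assert abs(auc.value - trapezoid) < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_auc([0.1, 0.9], [1, 1], n_boot=2)


class TestDiagnosticMetrics:
    def test_minimal_table_consistent_with_published_performance(self):
        """tp=14, fn=4, tn=12, fp=2 reproduces sensitivity 0.778,
        specificity 0.857, PPV 0.875, NPV 0.750 simultaneously."""
        m = ev.diagnostic_metrics(ev.ConfusionTable(tp=14, fp=2, fn=4, tn=12))
        assert round(m["sensitivity"].value, 3) == 0.778
        assert round(m["specificity"].value, 3) == 0.857
        assert round(m["ppv"].value, 3) == 0.875
        assert round(m["npv"].value, 3) == 0.750

    def test_consistent_tables_by_search(self):
        """Brute-force search over small tables: the family of 2x2 tables
        reproducing all four rounded values is generated by (7, 2, 6, 1);
        its double (14, 4, 12, 2) matches an 18/14-eye reference split."""
        target = (0.778, 0.857, 0.875, 0.750)
        consistent = []
        for tp in range(0, 21):
            for fn in range(0, 21):
                for tn in range(0, 21):
                    for fp in range(0, 21):
                        if 0 in (tp + fn, tn + fp, tp + fp, tn + fn):
                            continue
                        vals = (
                            round(tp / (tp + fn), 3),
                            round(tn / (tn + fp), 3),
                            round(tp / (tp + fp), 3),
                            round(tn / (tn + fn), 3),
                        )
                        if vals == target:
                            consistent.append((tp, fn, tn, fp))
        assert (14, 4, 12, 2) in consistent
        assert min(consistent, key=lambda t: sum(t)) == (7, 2, 6, 1)

    def test_perfect_classifier(self):
        m = ev.diagnostic_metrics(ev.ConfusionTable(tp=9, fp=0, fn=0, tn=11))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert m[name].value == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            ct = random_table(rng, need_margins=True)
            m = ev.diagnostic_metrics(ct)
            assert abs(m["sensitivity"].value - ct.tp / (ct.tp + ct.fn)) < 1e-12
            assert abs(m["specificity"].value - ct.tn / (ct.tn + ct.fp)) < 1e-12
            assert abs(m["ppv"].value - ct.tp / (ct.tp + ct.fp)) < 1e-12
            assert abs(m["npv"].value - ct.tn / (ct.tn + ct.fn)) < 1e-12

    def test_zero_denominator_flagged(self):
        m = ev.diagnostic_metrics(ev.ConfusionTable(tp=0, fp=0, fn=0, tn=10))
        assert not m["sensitivity"].defined
        assert not m["ppv"].defined
        assert m["specificity"].value == pytest.approx(1.0)

    def test_intervals_contain_estimate_and_tighten_with_n(self):
        small = ev.diagnostic_metrics(ev.ConfusionTable(tp=7, fp=3, fn=3, tn=7))
        large = ev.diagnostic_metrics(ev.ConfusionTable(tp=70, fp=30, fn=30, tn=70))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            s, l = small[name], large[name]
            assert s.lo <= s.value <= s.hi
            assert (l.hi - l.lo) < (s.hi - s.lo)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.5, 3.0, 4.7, 8.0, 9.0])
        assert ev.spearman_ci(x, np.exp(x)).value == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.array([1.0, 2.5, 3.0, 4.7, 8.0, 9.0])
        assert ev.spearman_ci(x, -x).value == pytest.approx(-1.0)

    def test_matches_hand_rank_oracle(self):
        x = np.array([3.1, 1.2, 4.5, 2.2, 5.9, 0.3])
        y = np.array([10.0, 3.0, 7.0, 9.0, 12.0, 1.0])
        # rank by hand (no ties), then Pearson on the ranks
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        expected = np.corrcoef(rx, ry)[0, 1]
        assert ev.spearman_ci(x, y).value == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        m = ev.spearman_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert not m.defined

    def test_interval_contains_estimate(self):
        rng = np.random.default_rng(12)
        x = rng.random(30)
        y = x + 0.3 * rng.random(30)
        m = ev.spearman_ci(x, y)
        assert m.lo <= m.value <= m.hi

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            ev.spearman_ci([1.0, 2.0], [1.0, 2.0])


class TestCohortEndToEnd:
    def test_oracle_labels_give_perfect_separation(self):
        from tearfilm.pipeline import run_cohort

        cases = run_cohort(n_cases=12, seed=5, mode="oracle")
        report = ev.evaluate_cases(cases, n_boot=100)
        assert report.sensitivity.value == pytest.approx(1.0)
        assert report.specificity.value == pytest.approx(1.0)
        assert report.spearman_r.value >= 0.9
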