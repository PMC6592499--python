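import numpy as np
import pytest
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from ppgaf.core import AF, SR
from ppgaf.errors import InputError, ParameterError
from ppgaf.evaluate import (
    burden_stratified_specificity,
    check_no_patient_leakage,
    cl_analysis,
    delong_test,
    metrics,
    roc_auc,
    roc_curve,
    split_scenario_a,
    split_scenario_b,
)


class TestSplits:
    def test_scenario_a_folds_partition_patients(self):
        pids = np.repeat([f"P{i:03d}" for i in range(75)], 4)
        plan = split_scenario_a(pids, k=5, repeats=2, seed=1)
        for rep in plan.folds:
            test_pids = [set(pids[f]) for f in rep]
            sizes = [len(s) for s in test_pids]
            assert sizes == [15] * 5
            assert set().union(*test_pids) == set(pids)
            for i in range(5):
                for j in range(i + 1, 5):
                    assert not test_pids[i] & test_pids[j]

    def test_scenario_a_no_leakage(self):
        pids = np.repeat([f"P{i:03d}" for i in range(20)], 7)
        plan = split_scenario_a(pids, k=5, repeats=3, seed=2)
        assert check_no_patient_leakage(plan, pids)

    def test_scenario_b_fold_sizes_and_training_share(self):
        labels = np.array([AF, SR] * 7000)
        plan = split_scenario_b(labels, k=5, repeats=1, seed=3)
        n = len(labels)
        for f, fold in enumerate(plan.folds[0]):
            assert len(fold) == n // 5
            train, test = plan.train_test(0, f, n)
            assert abs(len(train) / n - 0.8) < 1e-6
        all_test = np.concatenate(plan.folds[0])
        assert len(np.unique(all_test)) == n

    def test_scenario_b_deterministic_under_seed(self):
        labels = np.array([AF, SR] * 100)
        a = split_scenario_b(labels, k=5, repeats=2, seed=4)
        b = split_scenario_b(labels, k=5, repeats=2, seed=4)
        for ra, rb in zip(a.folds, b.folds):
            for fa, fb in zip(ra, rb):
                assert np.array_equal(fa, fb)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ParameterError):
            split_scenario_a(np.array(["P0", "P1"]), k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        labels = np.array([AF] * 5 + [SR] * 5)
        m = metrics(labels, labels)
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert m[k] == 100.0

    def test_always_af_predictor(self):
        labels = np.array([AF] * 5 + [SR] * 5)
        m = metrics(np.array([AF] * 10), labels)
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0
        assert np.isnan(m["npv"])  # no SR diagnoses -> undefined, not 0

    def test_hand_computed_confusion_matrix(self):
        # TP=9 FN=1 TN=8 FP=2
        labels = np.array([AF] * 10 + [SR] * 10)
        pred = np.array([AF] * 9 + [SR] + [AF] * 2 + [SR] * 8)
        m = metrics(pred, labels)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["ppv"] == pytest.approx(81.8, abs=0.05)
        assert m["npv"] == pytest.approx(88.9, abs=0.05)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_confusion_cells_sum_to_n(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([AF, SR], 50)
        pred = rng.choice([AF, SR], 50)
        m = metrics(pred, labels)
        assert m["tp"] + m["fn"] + m["tn"] + m["fp"] == 50


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array([AF] * 10 + [SR] * 10)
        scores = np.r_[np.linspace(2, 3, 10), np.linspace(0, 1, 10)]
        assert roc_auc(scores, labels) == 1.0

    def test_chance_level_on_independent_scores(self):
        rng = np.random.default_rng(1)
        labels = np.array([AF, SR] * 2000)
        scores = rng.normal(size=4000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.03

    def test_midrank_equals_trapezoidal_on_random_instances(self):
        # dual-computation oracle: sklearn's trapezoidal ROC area
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(10, 60)
            labels = np.array([AF, SR])[rng.integers(0, 2, n)]
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            fpr, tpr, _ = sk_roc_curve(labels == AF, scores)
            assert roc_auc(scores, labels) == pytest.approx(sk_auc(fpr, tpr), abs=1e-12)

    def test_own_roc_curve_matches_sklearn_area(self):
        rng = np.random.default_rng(3)
        labels = np.array([AF, SR])[rng.integers(0, 2, 300)]
        scores = rng.normal(size=300) + (labels == AF)
        fpr, tpr = roc_curve(scores, labels)
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(roc_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc(np.arange(5.0), np.array([AF] * 5))


class TestDeLong:
    def _paired(self, n=200, seed=4):
        rng = np.random.default_rng(seed)
        labels = np.array([AF] * (n // 2) + [SR] * (n // 2))
        s1 = rng.normal(size=n) + 1.2 * (labels == AF)
        s2 = 0.8 * s1 + rng.normal(size=n) * 0.6
        return s1, s2, labels

    def test_self_comparison_is_null(self):
        s1, _, labels = self._paired()
        res = delong_test(s1, s1, labels)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_monotone_transform_invariance(self):
        s1, _, labels = self._paired()
        res = delong_test(s1, np.exp(s1), labels)
        assert res.auc1 == pytest.approx(res.auc2, abs=1e-12)
        assert res.z == 0.0

    def test_variance_against_bootstrap_oracle(self):
        s1, s2, labels = self._paired(n=200, seed=5)
        res = delong_test(s1, s2, labels)
        rng = np.random.default_rng(6)
        pos = np.flatnonzero(labels == AF)
        neg = np.flatnonzero(labels == SR)
        diffs = []
        for _ in range(2000):
            bp = rng.choice(pos, len(pos), replace=True)
            bn = rng.choice(neg, len(neg), replace=True)
            idx = np.r_[bp, bn]
            lab = labels[idx]
            diffs.append(roc_auc(s1[idx], lab) - roc_auc(s2[idx], lab))
        boot_var = np.var(diffs, ddof=1)
        delong_var = res.var1 + res.var2 - 2 * res.cov
        assert delong_var == pytest.approx(boot_var, rel=0.15)

    def test_unpaired_inputs_rejected(self):
        s1, _, labels = self._paired()
        with pytest.raises(InputError):
            delong_test(s1[:-1], s1[:-1], labels)


class TestAucCiBinomial:
    def test_interval_brackets_auc_and_narrower_than_delong(self):
        from ppgaf.evaluate import auc_ci_binomial, auc_ci_delong

        rng = np.random.default_rng(12)
        labels = np.array([AF] * 60 + [SR] * 60)
        scores = rng.normal(size=120) + (labels == AF)
        auc, lo, hi = auc_ci_binomial(scores, labels)
        assert lo < auc < hi
        _, dlo, dhi = auc_ci_delong(scores, labels)
        assert (hi - lo) < (dhi - dlo)  # ignores comparison correlation


class TestPairedSpecificity:
    def test_identical_models_give_null_pair(self, small_windows):
        from ppgaf.evaluate import WindowDataset, paired_specificity_test, run_cv

        ds = WindowDataset.from_windows(small_windows[:200])
        res = run_cv(ds, models=("svm_rmssd_she", "svm_acf"), scenario="B",
                     k=5, repeats=1, seed=2)
        t, p = paired_specificity_test(res, "svm_rmssd_she", "svm_acf")
        assert np.isfinite(p) and 0 <= p <= 1
        # self-comparison: zero differences
        t2, p2 = paired_specificity_test(res, "svm_acf", "svm_acf")
        assert np.isnan(t2) or t2 == 0.0


class TestBurdenStratifiedSpecificity:
    def test_all_correct_gives_100_everywhere(self):
        labels = np.array([SR] * 40)
        burdens = np.linspace(0, 0.3, 40)
        out = burden_stratified_specificity(labels, labels, burdens)
        for v in out.values():
            if v["n"]:
                assert v["specificity"] == 100.0

    def test_bin_populations_partition_sr_windows(self):
        rng = np.random.default_rng(7)
        labels = np.array([SR] * 70 + [AF] * 30)
        pred = rng.choice([AF, SR], 100)
        burdens = rng.uniform(0, 0.35, 100)
        out = burden_stratified_specificity(pred, labels, burdens)
        assert sum(v["n"] for v in out.values()) == 70

    def test_empty_bin_reported_as_undefined(self):
        labels = np.array([SR] * 5)
        out = burden_stratified_specificity(labels, labels, np.zeros(5))
        assert out[">=20%"]["n"] == 0
        assert np.isnan(out[">=20%"]["specificity"])


class TestClAnalysis:
    def test_all_correct_at_full_confidence(self):
        out = cl_analysis(np.full(10, 100.0), np.ones(10, bool))
        assert out["cl_true_mean"] == 100.0
        assert out["cutoff_accuracy"] == 100.0
        assert np.isnan(out["cl_false_mean"])
        assert out["n_false"] == 0

    def test_calibrated_classifier_misdiagnosis_tracks_cl(self):
        # simulate a calibrated classifier: CL=c -> correct w.p. c/100
        rng = np.random.default_rng(8)
        cl = rng.uniform(50, 100, 20000)
        correct = rng.uniform(size=20000) < cl / 100
        out = cl_analysis(cl, correct)
        for row in out["misdiagnosis_by_bin"]:
            lo = float(row["bin"].split("-")[0])
            assert row["p_false"] == pytest.approx(100 - (lo + 2.5), abs=3.0)

    def test_mismatched_arrays_rejected(self):
        with pytest.raises(InputError):
            cl_analysis(np.ones(3), np.ones(4, bool))
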