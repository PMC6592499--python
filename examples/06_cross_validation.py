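"""Compare classifiers under patient-wise vs sample-wise cross-validation.

Scenario A folds by patient (the classifier always faces new patients);
Scenario B folds by window (the training distribution emulates the test
distribution). The gap between the two — especially in specificity on
high-PAC-burden windows — is the central evaluation of this package.

Uses a reduced cohort so the example runs in about two minutes.
"""

from ppgaf import CohortConfig, WindowDataset, generate_cohort, run_cv, segment

records = generate_cohort(15, CohortConfig(duration=300.0), seed=99)
windows = [w for r in records for w in segment(r)]
ds = WindowDataset.from_windows(windows)
print(f"dataset: {len(ds)} windows from 15 patients")

models = ("cnn1d", "svm_rmssd_she")
for scenario in ("A", "B"):
    res = run_cv(ds, models=models, scenario=scenario, k=5, repeats=1, seed=99)
    print(f"\nScenario {scenario}:")
    for m in models:
        rep = res.report(m)
        hi = rep["burden_specificity"][">=20%"]
        hi_txt = f"{hi['specificity']:.0f}% (n={hi['n']})" if hi["n"] else "n/a"
        print(
            f"  {m:14s} acc {rep['accuracy']:5.1f}%  spec {rep['specificity']:5.1f}%  "
            f"AUC {rep['auc_mean']:.3f}  spec@burden>=20%: {hi_txt}"
        )

print(
    "\nScenario B outperforms A for the deep classifier. At this reduced"
    "\nscale the high-burden bin holds only a handful of windows, so the"
    "\nburden-stratified numbers are noisy; at full scale (75 patients,"
    "\n15-min recordings — see tests/test_acceptance.py) the interval-"
    "\nfeature SVM collapses on high-burden SR windows while the deep"
    "\nclassifiers keep most of their specificity."
)
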