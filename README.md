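# ppgaf — atrial-fibrillation detection from photoplethysmography

Wearable pulse oximetry (photoplethysmography, PPG) is an attractive way to
screen for atrial fibrillation (AF), but the classical detectors — built on
inter-beat-interval irregularity features — fail exactly where screening
matters: sinus rhythm (SR) peppered with premature atrial complexes (PACs),
which is what recently cardioverted patients exhibit. `ppgaf` implements
and evaluates the full comparison between that older feature-based approach
and two compact deep classifiers that read the raw 30-s PPG waveform,
together with a confidence level attached to every diagnosis.

The package is aimed at researchers in physiological signal processing who
want a complete, reproducible test bed: because clinical pre-/post-
cardioversion recordings are not publicly available, a synthetic cohort
generator with ground-truth beat and PAC annotations stands in for the
clinical dataset, and every component is validated against that ground
truth.

## What is inside

| piece | summary |
|---|---|
| `ppgaf.simulate` | paired AF/SR PPG cohorts: lognormal i.i.d. AF intervals, respiratory-modulated SR, PACs with coupling interval < 0.85 × mean RR and compensatory pause, two-Gaussian pulse template, amplitude–interval coupling |
| `ppgaf.preprocess` | bias removal → 0.2–18 Hz zero-phase band-pass → 30-s windows, 20-s overlap → per-window z-score |
| `ppgaf.beats` | adaptive-threshold beat detection; PAC indicator (beat is a PAC iff its preceding interval < 0.85 × window mean interval); PAC burden = flagged/all beats |
| `ppgaf.baselines` | linear SVMs on RMSSD + Shannon entropy, on the signal autocorrelation at 30 lags, and their ensemble |
| `ppgaf.dl` | NumPy 1D-CNN (6 conv blocks, 5.3k params) and single-layer GRU RNN (4.7k params) with softmax output; confidence level CL = 100 × max(p_AF, p_SR) ∈ [50, 100]% |
| `ppgaf.evaluate` | patient-wise (Scenario A) vs sample-wise (Scenario B) 5-fold CV with repeats; accuracy/sens/spec/PPV/NPV; midrank AUC; DeLong test; PAC-burden-stratified specificity; true-vs-false CL analysis |

The diagnostic rates follow the standard definitions with AF as the
positive class, AUC is the midrank Mann–Whitney statistic, and correlated
AUCs are compared with the DeLong structural-components test.

## Worked example

`examples/` contains one short script per capability. For instance,
interval features on a small synthetic cohort
(`python examples/04_baseline_features.py`):

```
group         n  RMSSD (s)  ShE (nats)
AF          132      0.261        2.08
SR clean     73      0.069        1.00
SR w/ PACs   46      0.406        2.12
```

AF windows have high RMSSD and interval entropy, clean SR is low on both —
and SR windows with frequent PACs land in the AF region, which is why
interval-feature detectors misclassify them. Training the 1D-CNN on raw
waveforms (`python examples/05_train_deep_classifier.py`):

```
1D-CNN: 6 conv layers, 5282 parameters
loss: 0.693 (first epoch) -> 0.258 (last)
held-out accuracy on 88 windows from new patients: 98.9%

example diagnosis: p_AF=1.000 p_SR=0.000 -> AF at CL 100.0%
```

The confidence level is reported with every diagnosis; calls below ~95% CL
are the ones most likely to be wrong and worth confirming with an ECG.

At full scale (75 synthetic patients, 15-min recordings, run by the
acceptance test suite) the package reproduces the qualitative clinical
findings: sample-wise cross-validation outperforms patient-wise for the
deep classifiers; in SR windows with PAC burden ≥ 20% the deep classifiers
keep ~81–90% specificity while the RMSSD+ShE SVM collapses to a few
percent; and correct diagnoses carry far higher confidence levels than
errors (≈99% vs ≈80–92% mean CL).

A thin CLI mirrors the library for shell pipelines:

```bash
ppgaf simulate --n-patients 10 --duration 300 --seed 1 --out cohort/
ppgaf preprocess --in cohort/ --out windows/
ppgaf beats --in windows/ --out pacs.csv
ppgaf evaluate --data windows/ --models cnn1d,svm_rmssd_she --scenario b \
    --repeats 1 --seed 1 --out results/
```

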