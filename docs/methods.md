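# Methods

`ppgaf` detects atrial fibrillation (AF) from single-channel
photoplethysmography (PPG) and studies the failure mode that matters most in
practice: sinus rhythm (SR) contaminated by premature atrial complexes
(PACs), which mimic AF's interval irregularity. Because the paired
pre-/post-cardioversion clinical recordings such a study needs are not
publicly available, the package ships a synthetic cohort generator with
ground-truth annotations; every detector and classifier is exercised and
validated end to end on that cohort.

## Synthetic cohort model

Each synthetic patient contributes one AF recording ("pre-DCC", DCC =
direct-current cardioversion) and one SR recording ("post-DCC"), 15 min each
by default, sampled at `fs = 100 Hz`.

**AF inter-beat intervals** are i.i.d. draws from a lognormal with mean
`mean_rr` and coefficient of variation `rr_sd / mean_rr` (per-patient CV in
0.18–0.30), truncated to (0.25·mean_rr, 2.5·mean_rr). The i.i.d. choice is
the simplest model of an "irregularly irregular" rhythm: it gives lag-1
autocorrelation ≈ 0 by construction, which the tests assert.

**SR intervals** are `mean_rr · (1 + m·sin(2π·0.25·t)) + ε`,
ε ~ N(0, rr_sd²), with respiratory modulation depth `m` in 0.02–0.06 at 15
breaths/min — ordinary respiratory sinus arrhythmia.

**PACs** replace a scheduled sinus beat: the replaced beat moves to a
coupling interval `c = coupling_frac × local mean RR` after its predecessor
(coupling_frac drawn per-PAC from U(0.55, 0.80) unless fixed), followed by a
fully compensatory pause (`compensatory_frac = 2.0`: the next sinus beat
keeps its original time). Consequences used by the tests: total duration and
beat count are preserved exactly; every PAC's coupling interval is below
85% of the window mean RR, so the interval rule can always detect it; and
the post-PAC pause (≈1.2–1.45 × mean RR) is never itself flagged. PAC
counts are Poisson at the patient's `pac_rate`.

**Per-patient PAC rate** follows a four-component mixture
(probability, PACs/min): (0.58, 0), (0.14, U(0.3–1.5)), (0.14, U(2–5)),
(0.14, U(8–16)) — many patients with no ectopy, a minority with
bigeminy-like runs. The mixture was calibrated once, by direct measurement
on the frozen cohort seed, to the single published anchor available (≈30%
of SR windows containing at least one PAC; measured 31.4% at the frozen
seed) and then frozen. The shape of the burden histogram beyond that single
prevalence figure is uncalibrated — no per-bin counts exist to calibrate
against.

**Waveform.** One pulse per beat: a systolic Gaussian centred on the beat
time plus a smaller delayed dicrotic Gaussian, widths and delay scaled to
the surrounding interval so pulses never collide (6σ rendering support keeps
truncation error below 1e−7). Pulse amplitude is
`1 + amp_slope·(RR_prev − mean RR)/mean RR` (clipped to [0.3, 1.8]):
short preceding intervals — AF beats and PACs — produce attenuated pulses,
emulating reduced diastolic filling. Additive white Gaussian noise at
`noise_sd` (patient range 0.03–0.08 relative to unit pulse amplitude)
completes the record. Per-patient morphology (systolic width, dicrotic
amplitude/delay/width, amplitude slope) is jittered so patients genuinely
differ; that heterogeneity is what makes patient-wise cross-validation
harder than sample-wise.

**What the generator does not emulate:** motion artifacts (the emulated
protocol is supine and at rest), sensor drift/saturation, other ectopy
(ventricular premature complexes, atrial tachycardia), and any real
beat-to-beat morphology dynamics beyond the amplitude–interval coupling.
Passing tests therefore demonstrate the machinery is correct and the
qualitative orderings hold under controlled conditions; they do not certify
clinical accuracy on real recordings.

## Preprocessing

Bias removal (mean subtraction) → band-pass 0.2–18 Hz → segmentation into
30-s windows with 20-s overlap → per-window z-score. The filter is a
4th-order Butterworth applied forward–backward (zero phase), so beat
timing is undistorted; the band is applied to the full record before
cutting so filter transients are confined to the record edges. Window count
is `floor((duration − 30)/10) + 1` (88 per 15-min record). Windows inherit
the record's rhythm label; for annotated records each window also carries
its ground-truth PAC burden.

## Beat detection and the PAC indicator

Beats are local maxima of the conditioned window exceeding an adaptive
threshold (height and prominence at 0.30 × the 98th-percentile amplitude)
with a 0.25-s refractory period. A skewness gate (sample skewness ≥ 0.3)
rejects windows with no plausible pulse train before peak picking —
pulsatile PPG is strongly right-skewed, Gaussian noise is not. Windows with
fewer than 3 detected beats raise an error and are excluded from
interval-based analyses. The thresholds were tuned once against simulator
ground truth (per-beat sensitivity 0.99 / specificity 0.998 at default
noise) rather than trusted blindly.

The **PAC indicator** flags beat *i* iff
`interval[i−1] < 0.85 × mean(intervals in the window)` — strict inequality,
arithmetic mean over all intervals in the 30-s window including premature
ones, and the window's first beat is never flagged (it has no preceding
interval within the window). **PAC burden** is flagged beats / all beats in
the window. The indicator is validated per-beat against ground truth with
150-ms matching tolerance; the first annotated beat inside each window is
excluded from scoring since no windowed indicator can flag it.

## Baseline detectors

Three linear-kernel SVMs (C = 1.0, features z-scored on training-fold
statistics, liblinear):

* **RMSSD + ShE** — root-mean-square of successive interval differences,
  plus Shannon entropy of the interval histogram. ShE uses 16 equal-width
  bins spanning a *fixed* physiological range (0.3–1.5 s, out-of-range
  intervals clipped into the edge bins). Binning over each window's own
  interval range was considered and rejected: sinus jitter fills its own
  (tiny) range as uniformly as AF fills its wide one, which destroys the
  AF-vs-SR separation the feature exists for; a fixed range makes regular
  rhythms concentrate in one or two bins (low entropy) while AF spreads
  across many.
* **Autocorrelation** — the signal-domain ACF (FFT-based, biased
  estimator) at 30 lags evenly spaced in (0, 3] s.
* **Ensemble** — all of the above concatenated.

Features are computed from *detected* beats, not ground-truth annotations,
mirroring deployment.

## Deep classifiers

Implemented in NumPy (forward pass and analytic backpropagation, verified
against finite differences to ~1e−9 relative error), float32, Adam
(lr 3e−3), minibatch 128, 12 epochs, softmax cross-entropy. Classifier
input is the 30-s window resampled to 15 Hz (450 samples): PPG energy lies
below ~7 Hz, so beat timing and morphology survive while CPU cost drops
20-fold versus 100 Hz. Classifier heads are zero-initialized, so an
untrained model outputs the uninformative softmax (CL = 50%).

* **1D-CNN** — exactly 6 convolution blocks (kernel 7, stride 2, ReLU),
  channels 4→8→8→16→16→16, global average pooling, 2-unit softmax head;
  5282 parameters.
* **RNN** — the window framed into 30 one-second tokens (15 samples each)
  feeds a single-layer GRU with hidden size 32 whose final hidden state
  feeds the softmax head; 4674 parameters. A single recurrent layer plus
  the output layer is the reading adopted for the "shallow RNN" contract;
  the cell type (GRU) is a package choice.

Training on sets larger than `max_train_windows = 4000` uses a seeded,
label-stratified subsample — a CPU-cost control that leaves class balance
intact. Training is deterministic under a fixed seed and thread
configuration; the determinism test trains twice and requires bit-identical
probabilities.

**Confidence level.** `CL = 100 × max(p_AF, p_SR)`, the unique two-class
definition with the documented 50–100% range; symmetric under swapping the
pair. Diagnoses with CL ≥ 95% are treated as confident in the CL analysis.

## Evaluation

* **Scenario A** — 5-fold cross-validation over *patients* (no patient in
  both train and test of a fold); **Scenario B** — 5-fold over *windows*,
  stratified by label. Each scenario runs `repeats` independent fold
  assignments; reported rates average over all fold×repeat validations,
  with per-repeat values retained so the average is auditable. All models
  share fold assignments within a repeat, making paired AUC comparisons
  valid.
* **Rates** (AF positive): accuracy, sensitivity, specificity, PPV, NPV;
  a rate with an empty denominator is reported as undefined (NaN), never 0.
* **AUC** — midrank Mann–Whitney statistic (ties → midranks); the test
  suite cross-checks it against trapezoidal integration of the empirical
  ROC. Per-repeat AUCs are computed on that repeat's pooled scores and then
  averaged; a pooled-over-repeats AUC with a DeLong-SE 95% CI is also
  reported.
* **DeLong test** — structural-component covariance estimate for correlated
  ROC curves, two-sided normal p, CI = AUC ± 1.96·SE; self-comparison
  yields z = 0, p = 1 exactly. Validated against a stratified-bootstrap
  variance oracle. A Clopper–Pearson ("binomial exact") AUC CI is available
  as the crude alternative; it treats the n_pos×n_neg pairwise comparisons
  as independent and is therefore narrower than DeLong's.
* **Specificity comparisons across algorithms** use a paired t-test over
  the fold×repeat validations (all models share fold assignments within a
  repeat, so pairing is valid).
* **Burden-stratified specificity** — SR test windows binned by
  ground-truth PAC burden at 0–5–10–15–20+ %; empty bins reported as
  undefined with n = 0.
* **CL analysis** — mean/median CL over correct ("true CL") vs incorrect
  ("false CL") diagnoses, accuracy restricted to CL ≥ 95%, share of
  diagnoses above the cutoff, and the per-CL-bin misdiagnosis probability
  (for a calibrated classifier, ≈ 100 − CL).

## Frozen acceptance conditions and problem sizes

The end-to-end acceptance experiment uses 75 patients × two 900-s
recordings (13,200 windows), both scenarios at k = 5 with 2 repeats, seed
20190606, models 1D-CNN, RNN and the RMSSD+ShE SVM. Representative outcome
at that seed: Scenario-B AUC 0.999 (CNN) / 0.9995 (RNN); Scenario-B
specificity above Scenario-A for both; in the ≥20%-burden bin the deep
classifiers hold 81/90% specificity while the RMSSD+ShE SVM drops to ~4%;
mean true CL ≈ 99% vs false CL ≈ 80–92%. These reproduce the *direction* of
the published clinical findings; the absolute clinical values are not
reproducible without the clinical recordings, which is why the acceptance
suite asserts orderings and bounds rather than point values.

## Numerical choices and degenerate inputs

* Strict inequality at the 0.85 PAC boundary; an interval exactly at the
  threshold is not a PAC.
* Constant signals raise degenerate-input errors in `normalize` and
  `autocorr_features`; constant intervals give RMSSD 0 and ShE 0.
* Records shorter than one window yield an empty window list with a warning
  rather than an error.
* `insert_pacs` keeps ≥2 sinus beats between PACs and skips a candidate
  site when the coupling interval would collide with a neighbour, so
  realized counts can sit slightly below the Poisson draw at extreme rates.
* Seeds: every stochastic component derives its generator from an explicit
  `SeedSequence`; patient streams are spawned, so cohorts are reproducible
  sample-for-sample.

## Known limitations

* The generator's realism ceiling: real PPG exhibits motion artifacts,
  drift, and richer morphology variation; the reported metrics quantify the
  synthetic task, not clinical performance.
* The beat detector is tuned for the synthetic template family; real
  recordings would need re-tuning and an artifact/quality gate.
* The exact feature definitions of the referenced historical detectors
  (entropy binning, autocorrelation lag structure) are not public in the
  source this package follows; the configurations here are declared package
  defaults, not claims about those references.
* Scenario-B results overstate deployment performance by design — that
  contrast (generalization to new patients vs matched distributions) is the
  point of running both.
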