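"""Interval-irregularity features that older AF detectors rely on.

RMSSD and Shannon entropy of detected inter-beat intervals separate AF from
clean sinus rhythm, but premature atrial complexes inflate both on SR
windows — the confounder that motivates waveform-level classifiers.
"""

import numpy as np

from ppgaf import CohortConfig, extract_features, generate_cohort, segment
from ppgaf.errors import InsufficientBeatsError

records = generate_cohort(6, CohortConfig(duration=240.0), seed=21)
windows = [w for r in records for w in segment(r)]

groups = {
    "AF": lambda w: w.label == "AF",
    "SR clean": lambda w: w.label == "SR" and not w.burden,
    "SR w/ PACs": lambda w: w.label == "SR" and w.burden and w.burden > 0.05,
}
print(f"{'group':10s} {'n':>4s} {'RMSSD (s)':>10s} {'ShE (nats)':>11s}")
for name, keep in groups.items():
    feats = []
    for w in filter(keep, windows):
        try:
            feats.append(extract_features(w))
        except InsufficientBeatsError:
            continue
    rms = np.median([f.rmssd for f in feats])
    she = np.median([f.she for f in feats])
    print(f"{name:10s} {len(feats):4d} {rms:10.3f} {she:11.2f}")

print(
    "\nAF windows show high RMSSD and entropy; clean SR is low on both."
    "\nSR windows with frequent PACs drift toward the AF region, which is"
    "\nexactly where interval-feature SVMs lose specificity."
)
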