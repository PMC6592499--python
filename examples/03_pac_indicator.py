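"""Detect beats and flag premature atrial complexes with the 85% rule.

A beat is a PAC when its preceding inter-beat interval is shorter than 85%
of the window's mean interval. The indicator is validated against the
simulator's ground-truth PAC annotations.
"""

from ppgaf import RhythmParams, detect_beats, detect_pacs, segment, simulate_record
from ppgaf.beats import validate_indicator

record = simulate_record(
    RhythmParams(rhythm="SR", pac_rate=6.0, duration=600.0, seed=3), patient_id="P003"
)
windows = segment(record)

w = next(win for win in windows if win.burden and win.burden > 0)
rr = detect_beats(w)
res = detect_pacs(rr)
print(
    f"window {w.window_index}: {res.n_beats} beats, {res.n_pac} PACs, "
    f"burden {res.burden:.1%} (ground truth {w.burden:.1%})"
)

val = validate_indicator([record], [windows])
print(
    f"\nindicator vs ground truth over {val.n_windows} windows: "
    f"sensitivity {val.sensitivity:.1%}, specificity {val.specificity:.1%} "
    f"({val.n_true_pac} true PACs)"
)
print(
    "\nSensitivity is the share of true PACs flagged; specificity the share"
    "\nof normal beats left unflagged. Both are near 1 at default noise"
    "\nbecause every synthetic PAC violates the 85% rule by construction."
)
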