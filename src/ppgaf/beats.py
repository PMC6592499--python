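"""Beat detection, the PAC indicator, and PAC-burden computation.

The PAC indicator applies a single interval rule: a beat is a premature
atrial complex (PAC) when the interval from the previous beat is strictly
less than 85% of the average interval in the window. The "average interval"
is the arithmetic mean of all intervals in the window, premature ones
included. The first beat of a window can never be flagged — it has no
preceding interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import PacResult, PPGRecord, RRSeries, WindowSample
from .errors import InsufficientBeatsError

PAC_THRESHOLD = 0.85
REFRACTORY_S = 0.25
MATCH_TOL_S = 0.150  # detected beat matches a true beat within this tolerance


def detect_beats(window: WindowSample) -> RRSeries:
    """Detect pulse peaks in a normalized window.

    Peaks are local maxima of the (already band-passed, z-scored) signal
    exceeding an adaptive amplitude threshold, separated by a 0.25-s
    refractory period. Pulsatile PPG is strongly right-skewed (sparse
    upward pulses over a baseline); a skewness gate rejects windows with no
    plausible pulse train before peak picking.

    Raises
    ------
    InsufficientBeatsError
        If fewer than 3 beats are found; such windows are excluded from
        interval-based analyses.
    """
    x = np.asarray(window.samples, dtype=float)
    if x.size == 0 or stats.skew(x) < 0.3:
        raise InsufficientBeatsError("window has no plausible pulse train")
    # adaptive threshold from the upper envelope; robust to amplitude variation
    hi = np.percentile(x, 98)
    peaks, _ = sps.find_peaks(
        x,
        height=0.30 * hi,
        prominence=0.30 * hi,
        distance=max(1, int(round(REFRACTORY_S * window.fs))),
    )
    if len(peaks) < 3:
        raise InsufficientBeatsError(f"only {len(peaks)} beats detected")
    return RRSeries(beat_times=window.start_time + peaks / window.fs)


def detect_pacs(rr: RRSeries, threshold: float = PAC_THRESHOLD) -> PacResult:
    """Apply the 85% interval rule to an RR series.

    Beat ``i`` (i >= 1) is flagged iff ``intervals[i-1] < threshold * mean(intervals)``.
    """
    intervals = rr.intervals
    if len(intervals) < 2:
        raise InsufficientBeatsError("PAC rule needs at least 2 intervals")
    mean_rr = intervals.mean()
    flags = np.zeros(rr.n_beats, dtype=bool)
    flags[1:] = intervals < threshold * mean_rr  # strict inequality
    return PacResult(n_beats=rr.n_beats, n_pac=int(flags.sum()), flags=flags)


def pac_burden(result: PacResult) -> float:
    """PAC burden: flagged beats divided by all beats in the window."""
    return result.burden


@dataclass
class IndicatorValidation:
    """Per-beat agreement of the detected PAC flags with ground truth."""

    sensitivity: float
    specificity: float
    n_true_pac: int
    n_true_normal: int
    n_windows: int
    n_excluded: int


def validate_indicator(
    records: list[PPGRecord],
    windows_by_record: list[list[WindowSample]],
    threshold: float = PAC_THRESHOLD,
) -> IndicatorValidation:
    """Validate detect_beats + detect_pacs against simulator ground truth.

    A detected beat is matched to the nearest annotated beat within 150 ms;
    sensitivity is the fraction of true PACs whose matched detected beat is
    flagged, specificity the fraction of true normal beats left unflagged.
    The first annotated beat inside each window is excluded from scoring —
    it has no preceding interval within the window, so no indicator can
    flag it. Beats closer to the window end than the matching tolerance are
    likewise excluded: their pulse is truncated by the window boundary.
    """
    tp = fn = tn = fp = 0
    n_excluded = n_windows = 0
    for record, windows in zip(records, windows_by_record):
        if record.beat_times is None or record.pac_flags is None:
            continue
        for w in windows:
            n_windows += 1
            try:
                rr = detect_beats(w)
            except InsufficientBeatsError:
                n_excluded += 1
                continue
            res = detect_pacs(rr, threshold=threshold)
            t0, t1 = w.start_time, w.start_time + len(w.samples) / w.fs
            m = (record.beat_times >= t0) & (record.beat_times < t1 - MATCH_TOL_S)
            true_times = record.beat_times[m][1:]  # first beat: no prior interval
            true_flags = record.pac_flags[m][1:]
            if len(true_times) == 0:
                continue
            # match each true beat to nearest detected beat
            det_times = rr.beat_times
            idx = np.searchsorted(det_times, true_times)
            idx = np.clip(idx, 1, len(det_times) - 1)
            left, right = det_times[idx - 1], det_times[idx]
            nearest = np.where(
                np.abs(true_times - left) <= np.abs(true_times - right), idx - 1, idx
            )
            dist = np.abs(det_times[nearest] - true_times)
            matched = dist <= MATCH_TOL_S
            det_flag = res.flags[nearest]
            for is_pac, ok, flagged in zip(true_flags, matched, det_flag):
                pred = bool(ok and flagged)
                if is_pac:
                    tp += pred
                    fn += not pred
                else:
                    fp += pred
                    tn += not pred
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return IndicatorValidation(
        sensitivity=sens,
        specificity=spec,
        n_true_pac=tp + fn,
        n_true_normal=tn + fp,
        n_windows=n_windows,
        n_excluded=n_excluded,
    )
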