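"""Signal conditioning and window extraction.

Pipeline order: bias removal -> zero-phase band-pass (0.2-18 Hz) ->
segmentation into 30-s windows with 20-s overlap -> per-window z-score
normalization. The record is filtered once in full before cutting so the
filter transient is confined to the record edges rather than repeated at
every window boundary.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .core import PPGRecord, WindowSample
from .errors import DegenerateInputError, InputError, ParameterError

log = logging.getLogger(__name__)

BAND_LO_HZ = 0.2
BAND_HI_HZ = 18.0
WINDOW_S = 30.0
OVERLAP_S = 20.0


def remove_bias(signal: np.ndarray) -> np.ndarray:
    """Subtract the mean so the output is zero-mean."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InputError("signal is empty")
    return x - x.mean()


def bandpass(
    signal: np.ndarray, fs: float, lo: float = BAND_LO_HZ, hi: float = BAND_HI_HZ
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    A 4th-order Butterworth applied forward-backward (``sosfiltfilt``), so
    beat timing is not shifted — the PAC indicator depends on interval
    ratios, not absolute delay, but zero phase keeps detected beats aligned
    with ground-truth annotations.
    """
    if fs <= 2 * hi:
        raise ParameterError(f"fs must exceed 2*hi = {2 * hi} Hz, got {fs}")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InputError("signal is empty")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def normalize(signal: np.ndarray) -> np.ndarray:
    """Per-window z-score: zero mean, unit standard deviation."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InputError("signal is empty")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant signal cannot be normalized")
    return (x - x.mean()) / sd


def segment(
    record: PPGRecord,
    win: float = WINDOW_S,
    overlap: float = OVERLAP_S,
    burden_fn=None,
) -> list[WindowSample]:
    """Cut a record into overlapping, preprocessed windows.

    Windows start at multiples of ``win - overlap``; each inherits the
    record's rhythm label. When the record carries ground-truth beat
    annotations, each window's true PAC burden (flagged beats / beats in the
    window) is attached.

    Returns an empty list (with a warning) for records shorter than ``win``.
    """
    if not 0 <= overlap < win:
        raise ParameterError("overlap must satisfy 0 <= overlap < win")
    duration = record.duration
    if duration < win:
        log.warning(
            "record %s/%s shorter than %gs window; no windows produced",
            record.patient_id,
            record.phase,
            win,
        )
        return []
    step = win - overlap
    n_win = int(np.floor((duration - win) / step)) + 1
    filtered = bandpass(remove_bias(record.samples), record.fs)
    wlen = int(round(win * record.fs))
    out: list[WindowSample] = []
    for k in range(n_win):
        start = k * step
        i0 = int(round(start * record.fs))
        seg = filtered[i0 : i0 + wlen]
        burden = _window_burden(record, start, start + win)
        out.append(
            WindowSample(
                samples=normalize(seg),
                fs=record.fs,
                start_time=start,
                label=record.label,
                patient_id=record.patient_id,
                window_index=k,
                burden=burden,
            )
        )
    return out


def _window_burden(record: PPGRecord, t0: float, t1: float) -> float | None:
    """Ground-truth PAC burden of the window [t0, t1), if annotated."""
    if record.beat_times is None or record.pac_flags is None:
        return None
    m = (record.beat_times >= t0) & (record.beat_times < t1)
    n = int(m.sum())
    if n == 0:
        return 0.0
    return float(record.pac_flags[m].sum() / n)


def n_windows(duration: float, win: float = WINDOW_S, overlap: float = OVERLAP_S) -> int:
    """Window count for a record of the given duration."""
    if duration < win:
        return 0
    return int(np.floor((duration - win) / (win - overlap))) + 1
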