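"""Shared domain containers.

The package models one clinical workflow: paired 15-minute fingertip
photoplethysmography (PPG) recordings per patient — one in atrial
fibrillation (AF) before electrical cardioversion, one in sinus rhythm (SR)
afterwards — cut into 30-second windows and classified AF vs SR. SR
recordings frequently carry premature atrial complexes (PACs), the main
confounder for interval-based AF detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

AF = "AF"
SR = "SR"
PRE_DCC = "pre_dcc"
POST_DCC = "post_dcc"


@dataclass
class PPGRecord:
    """One continuous single-channel PPG recording with annotations.

    ``beat_times``/``pac_flags`` are ground-truth annotations (available for
    synthetic data); ``pac_flags[i]`` marks whether the beat at
    ``beat_times[i]`` is a premature atrial complex.
    """

    samples: np.ndarray
    fs: float
    patient_id: str
    phase: str  # "pre_dcc" | "post_dcc"
    label: str  # "AF" | "SR"
    beat_times: np.ndarray | None = None
    pac_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if np.any(np.diff(self.beat_times) <= 0):
                raise InputError("beat_times must be strictly increasing")
        if self.pac_flags is not None:
            self.pac_flags = np.asarray(self.pac_flags, dtype=bool)
            if self.beat_times is None or len(self.pac_flags) != len(self.beat_times):
                raise InputError("pac_flags must align with beat_times")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class RRSeries:
    """Ordered beat times with inter-beat (RR) intervals and PAC flags.

    ``pac_flags`` aligns with ``beat_times``; a flagged beat is the one that
    *terminates* a short interval.
    """

    beat_times: np.ndarray
    pac_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise InputError("beat_times must be strictly increasing")
        if self.pac_flags is None:
            self.pac_flags = np.zeros(len(self.beat_times), dtype=bool)
        else:
            self.pac_flags = np.asarray(self.pac_flags, dtype=bool)
            if len(self.pac_flags) != len(self.beat_times):
                raise InputError("pac_flags must align with beat_times")

    @property
    def intervals(self) -> np.ndarray:
        """RR intervals in seconds; intervals[i] = beat_times[i+1] - beat_times[i]."""
        return np.diff(self.beat_times)

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)


@dataclass
class WindowSample:
    """One preprocessed, normalized 30-s PPG segment with its label."""

    samples: np.ndarray
    fs: float
    start_time: float
    label: str
    patient_id: str
    window_index: int
    burden: float | None = None  # ground-truth PAC burden when known

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class PacResult:
    """Outcome of the PAC indicator on one window."""

    n_beats: int
    n_pac: int
    flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def burden(self) -> float:
        """Fraction of beats flagged as PACs, in [0, 1]."""
        if self.n_beats <= 0:
            raise InputError("burden undefined for zero beats")
        return self.n_pac / self.n_beats


@dataclass
class Diagnosis:
    """Classifier output for one window: softmax pair, label, confidence level."""

    p_af: float
    p_sr: float
    predicted: str
    cl: float  # percentage in [50, 100]
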