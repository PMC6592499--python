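"""Feature-based AF detectors used as comparison baselines.

Three linear-kernel SVM detectors, following earlier PPG AF-detection work:

* RMSSD + Shannon entropy of the inter-beat-interval histogram,
* the signal-domain autocorrelation function sampled at fixed lags,
* their ensemble (all features concatenated).

Features come from *detected* beats (the beat detector in
:mod:`ppgaf.beats`), not ground-truth annotations, mirroring deployment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .beats import detect_beats
from .core import RRSeries, WindowSample
from .errors import DegenerateInputError, InputError, InsufficientBeatsError

N_SHE_BINS = 16
SHE_RANGE_S = (0.3, 1.5)  # physiological interval range spanned by the bins
ACF_MAX_LAG_S = 3.0
N_ACF_LAGS = 30
SVM_C = 1.0


def rmssd(rr: RRSeries) -> float:
    """Root-mean-square of successive RR-interval differences, seconds."""
    intervals = rr.intervals
    if len(intervals) < 2:
        raise InsufficientBeatsError("RMSSD needs at least 2 intervals")
    d = np.diff(intervals)
    return float(np.sqrt(np.mean(d**2)))


def shannon_entropy(
    rr: RRSeries,
    n_bins: int = N_SHE_BINS,
    bin_range: tuple[float, float] = SHE_RANGE_S,
) -> float:
    """Shannon entropy (nats) of the interval histogram.

    Intervals are binned into ``n_bins`` equal-width bins spanning a fixed
    physiological interval range (default 0.3-1.5 s; out-of-range intervals
    are clipped into the edge bins). A fixed range is what makes the feature
    discriminative: regular sinus intervals concentrate in one or two bins
    (low entropy) while AF intervals spread across many (high entropy).
    Constant intervals give 0 by convention.
    """
    intervals = rr.intervals
    if len(intervals) < 2:
        raise InsufficientBeatsError("entropy needs at least 2 intervals")
    clipped = np.clip(intervals, bin_range[0], bin_range[1])
    counts, _ = np.histogram(clipped, bins=n_bins, range=bin_range)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def autocorr_features(
    window: WindowSample, max_lag: float = ACF_MAX_LAG_S, n_lags: int = N_ACF_LAGS
) -> np.ndarray:
    """Normalized signal autocorrelation at ``n_lags`` lags in (0, max_lag].

    A regular pulse train has a strong ACF peak near its beat period; AF
    smears it out. ACF(0) = 1 by normalization; returned values lie in
    [-1, 1].
    """
    x = np.asarray(window.samples, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DegenerateInputError("constant window has no autocorrelation")
    n = len(x)
    # FFT-based full ACF, biased estimator
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    s = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(s * np.conj(s), nfft)[:n] / denom
    lags = np.unique(np.round(np.linspace(1, max_lag * window.fs, n_lags)).astype(int))
    lags = lags[lags < n]
    vals = acf[lags]
    if len(vals) < n_lags:  # short windows: pad with the last value
        vals = np.pad(vals, (0, n_lags - len(vals)), mode="edge")
    return vals


@dataclass
class FeatureVector:
    """Per-window baseline features and their source identity."""

    rmssd: float
    she: float
    acf: np.ndarray
    patient_id: str
    window_index: int
    label: str

    @property
    def interval_features(self) -> np.ndarray:
        return np.array([self.rmssd, self.she])

    @property
    def ensemble(self) -> np.ndarray:
        """Concatenated [rmssd, she, acf...] for the ensemble SVM."""
        return np.concatenate([[self.rmssd, self.she], self.acf])


def extract_features(window: WindowSample) -> FeatureVector:
    """Compute all baseline features for one window (detected beats).

    Raises :class:`InsufficientBeatsError` when no usable pulse train is
    found; callers exclude such windows from baseline evaluation.
    """
    rr = detect_beats(window)
    return FeatureVector(
        rmssd=rmssd(rr),
        she=shannon_entropy(rr),
        acf=autocorr_features(window),
        patient_id=window.patient_id,
        window_index=window.window_index,
        label=window.label,
    )


FEATURE_SETS = {
    "rmssd_she": lambda fv: fv.interval_features,
    "acf": lambda fv: fv.acf,
    "ensemble": lambda fv: fv.ensemble,
}


def feature_matrix(fvs: list[FeatureVector], feature_set: str = "ensemble") -> np.ndarray:
    try:
        getter = FEATURE_SETS[feature_set]
    except KeyError:
        raise InputError(f"unknown feature set {feature_set!r}") from None
    return np.vstack([getter(fv) for fv in fvs])


def features_to_csv(fvs: list[FeatureVector], path) -> None:
    """Persist per-window features as CSV (one row per window)."""
    import pandas as pd

    rows = []
    for fv in fvs:
        row = {
            "patient_id": fv.patient_id,
            "window_index": fv.window_index,
            "label": fv.label,
            "rmssd": fv.rmssd,
            "she": fv.she,
        }
        row.update({f"acf_{i:02d}": v for i, v in enumerate(fv.acf)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def save_svm(clf: Pipeline, path, feature_set: str, seed: int | None = None) -> None:
    """Serialize a fitted SVM with a JSON metadata sidecar."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    joblib.dump(clf, path.with_suffix(".joblib"))
    meta = {
        "feature_set": feature_set,
        "c": float(clf.named_steps["svm"].C),
        "kernel": "linear",
        "seed": seed,
        "n_features": int(clf.named_steps["scale"].n_features_in_),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_svm(path) -> tuple[Pipeline, dict]:
    """Load a serialized SVM and its metadata."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    clf = joblib.load(path.with_suffix(".joblib"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return clf, meta


def train_svm(features: np.ndarray, labels: np.ndarray, c: float = SVM_C) -> Pipeline:
    """Fit a linear-kernel SVM with features standardized on training stats.

    Returns an sklearn pipeline whose ``decision_function`` provides scores
    for ROC analysis. Deterministic given the data and ``c``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InputError("SVM training needs both classes present")
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=c, dual=False)),
        ]
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf
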