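"""Cross-validation scenarios and the full evaluation machinery.

Two 5-fold cross-validation designs distinguish how hard the task is:

* **Scenario A** (patient-wise): patients are partitioned into folds, so a
  classifier always faces new patients at test time.
* **Scenario B** (sample-wise): windows are partitioned regardless of
  patient, so a patient's windows may appear in both train and test —
  emulating a training set whose distribution matches the test set.

Each scenario is repeated with fresh fold assignments and results averaged
over all fold x repeat validations. Diagnostic metrics treat AF as the
positive class. AUC is computed as the midrank Mann-Whitney statistic;
correlated AUCs are compared with the DeLong test. Specificity is
additionally stratified by the PAC burden of SR test windows, and the
confidence level (CL) of correct vs incorrect diagnoses is summarized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import baselines as bl
from . import dl as dlmod
from .core import AF, SR, WindowSample
from .errors import InputError, InsufficientBeatsError, ParameterError

BURDEN_BIN_EDGES_PCT = (0.0, 5.0, 10.0, 15.0, 20.0, np.inf)
CL_CUTOFF_PCT = 95.0

MODEL_NAMES = ("cnn1d", "rnn", "svm_rmssd_she", "svm_acf", "svm_ensemble")


# ---------------------------------------------------------------------------
# Cross-validation plans
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    """Fold assignments for one scenario: ``folds[repeat][fold]`` is an
    array of *test* window indices."""

    scenario: str
    k: int
    repeats: int
    folds: list[list[np.ndarray]]
    seed: int

    def train_test(self, repeat: int, fold: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[repeat][fold]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        return np.flatnonzero(mask), test


def split_scenario_a(
    patient_ids: np.ndarray, k: int = 5, repeats: int = 10, seed: int = 0
) -> CvPlan:
    """Patient-wise k-fold plan: no patient straddles train and test."""
    patient_ids = np.asarray(patient_ids)
    unique = np.unique(patient_ids)
    if len(unique) < k:
        raise ParameterError(f"need at least k={k} patients, got {len(unique)}")
    ss = np.random.SeedSequence([seed, 0xA])
    folds: list[list[np.ndarray]] = []
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        order = rng.permutation(unique)
        groups = np.array_split(order, k)
        folds.append(
            [np.flatnonzero(np.isin(patient_ids, g)) for g in groups]
        )
    return CvPlan(scenario="A", k=k, repeats=repeats, folds=folds, seed=seed)


def split_scenario_b(
    labels: np.ndarray, k: int = 5, repeats: int = 10, seed: int = 0
) -> CvPlan:
    """Sample-wise k-fold plan, stratified by label to keep folds balanced."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ParameterError(f"need at least k={k} windows, got {len(labels)}")
    ss = np.random.SeedSequence([seed, 0xB])
    folds: list[list[np.ndarray]] = []
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        per_fold: list[list[np.ndarray]] = [[] for _ in range(k)]
        for cls in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            for f, part in enumerate(np.array_split(idx, k)):
                per_fold[f].append(part)
        folds.append([np.sort(np.concatenate(parts)) for parts in per_fold])
    return CvPlan(scenario="B", k=k, repeats=repeats, folds=folds, seed=seed)


def check_no_patient_leakage(plan: CvPlan, patient_ids: np.ndarray) -> bool:
    """True iff no patient appears in both train and test of any fold."""
    patient_ids = np.asarray(patient_ids)
    n = len(patient_ids)
    for r in range(plan.repeats):
        for f in range(plan.k):
            train, test = plan.train_test(r, f, n)
            if set(patient_ids[train]) & set(patient_ids[test]):
                return False
    return True


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def metrics(pred: np.ndarray, labels: np.ndarray) -> dict:
    """Core diagnostic rates in percent, AF as the positive class.

    accuracy = correct / all; sensitivity = true AF / AF-labeled;
    specificity = true SR / SR-labeled; PPV = true AF / diagnosed AF;
    NPV = true SR / diagnosed SR. A rate whose denominator is empty is
    reported as NaN (undefined), never as 0.
    """
    pred = np.asarray(pred)
    labels = np.asarray(labels)
    if len(pred) == 0 or len(pred) != len(labels):
        raise InputError("predictions and labels must be equal-length and non-empty")
    tp = int(np.sum((pred == AF) & (labels == AF)))
    fn = int(np.sum((pred == SR) & (labels == AF)))
    tn = int(np.sum((pred == SR) & (labels == SR)))
    fp = int(np.sum((pred == AF) & (labels == SR)))

    def rate(num, den):
        return 100.0 * num / den if den else float("nan")

    return {
        "accuracy": rate(tp + tn, len(pred)),
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "n": len(pred),
    }


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC points (FPR, TPR), thresholds descending."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == AF
    order = np.argsort(-scores, kind="mergesort")
    y = y[order]
    s = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((~y).sum(), 1)]
    return fpr, tpr


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the midrank Mann-Whitney statistic (ties get midranks)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == AF
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _delong_components(scores: np.ndarray, y_pos: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y_pos]
    neg = scores[~y_pos]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    var1: float
    var2: float
    cov: float
    z: float
    p: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]


def delong_test(
    scores_1: np.ndarray, scores_2: np.ndarray, labels: np.ndarray
) -> DeLongResult:
    """DeLong comparison of two correlated AUCs on paired scores.

    Variances and the covariance come from the structural components of the
    Mann-Whitney statistic; the two-sided p uses a normal approximation and
    each CI is AUC +/- 1.96 SE.
    """
    scores_1 = np.asarray(scores_1, dtype=float)
    scores_2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels)
    if scores_1.shape != scores_2.shape or scores_1.shape != labels.shape:
        raise InputError("DeLong requires paired scores on identical test windows")
    y_pos = labels == AF
    if y_pos.all() or not y_pos.any():
        raise InputError("DeLong needs both classes present")
    auc1, v10_1, v01_1 = _delong_components(scores_1, y_pos)
    auc2, v10_2, v01_2 = _delong_components(scores_2, y_pos)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    s = s10 / m + s01 / n
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    diff = auc1 - auc2
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    se1, se2 = np.sqrt(s[0, 0]), np.sqrt(s[1, 1])
    return DeLongResult(
        auc1=float(auc1),
        auc2=float(auc2),
        var1=float(s[0, 0]),
        var2=float(s[1, 1]),
        cov=float(s[0, 1]),
        z=float(z),
        p=min(p, 1.0),
        ci1=(float(auc1 - 1.96 * se1), float(auc1 + 1.96 * se1)),
        ci2=(float(auc2 - 1.96 * se2), float(auc2 + 1.96 * se2)),
    )


def auc_ci_delong(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """AUC with DeLong-SE 95% CI for a single classifier."""
    y_pos = np.asarray(labels) == AF
    auc, v10, v01 = _delong_components(np.asarray(scores, dtype=float), y_pos)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    se = np.sqrt(var)
    return float(auc), float(auc - 1.96 * se), float(auc + 1.96 * se)


def auc_ci_binomial(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """AUC with a Clopper-Pearson ("binomial exact") 95% CI.

    Treats the AUC as a success proportion over the n_pos x n_neg pairwise
    comparisons. This ignores the correlation between comparisons sharing a
    window, so the interval is narrower than DeLong's; it is provided as
    the crude alternative, with the DeLong CI (:func:`auc_ci_delong`) as
    the default.
    """
    auc = roc_auc(scores, labels)
    y = np.asarray(labels) == AF
    n = int(y.sum()) * int((~y).sum())
    k = auc * n
    lo = stats.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
    return float(auc), float(lo), float(hi)


def burden_stratified_specificity(
    pred: np.ndarray,
    labels: np.ndarray,
    burdens: np.ndarray,
    bin_edges_pct: tuple = BURDEN_BIN_EDGES_PCT,
) -> dict:
    """Specificity per PAC-burden bin over SR-labeled test windows.

    Burdens are fractions in [0, 1]; bin edges are in percent (default
    0-5-10-15-20+). Empty bins are reported with specificity NaN and n=0.
    """
    pred = np.asarray(pred)
    labels = np.asarray(labels)
    burdens = np.asarray(burdens, dtype=float)
    sr = labels == SR
    out = {}
    edges = np.asarray(bin_edges_pct, dtype=float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        name = f"{lo:g}-{hi:g}%" if np.isfinite(hi) else f">={lo:g}%"
        m = sr & (burdens * 100 >= lo) & (burdens * 100 < hi)
        n = int(m.sum())
        spec = 100.0 * np.mean(pred[m] == SR) if n else float("nan")
        out[name] = {"specificity": spec, "n": n}
    return out


def cl_analysis(
    cls_pct: np.ndarray,
    correct: np.ndarray,
    cutoff: float = CL_CUTOFF_PCT,
    bin_width: float = 5.0,
) -> dict:
    """Summarize confidence levels of correct vs incorrect diagnoses.

    Reports mean/median CL for true (correct) and false (incorrect)
    diagnoses, the accuracy restricted to CL >= cutoff, the share of
    diagnoses at or above the cutoff, and the per-CL-bin misdiagnosis
    probability (a calibration profile: for a calibrated classifier the
    misdiagnosis probability in bin b is about 100 - b).
    """
    cls_pct = np.asarray(cls_pct, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if cls_pct.shape != correct.shape:
        raise InputError("CL and correctness arrays must align")
    true_cl = cls_pct[correct]
    false_cl = cls_pct[~correct]
    above = cls_pct >= cutoff
    bins = np.arange(50.0, 100.0 + bin_width, bin_width)
    mis = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        m = (cls_pct >= lo) & (cls_pct < hi if hi < 100 else cls_pct <= hi)
        mis.append(
            {
                "bin": f"{lo:g}-{hi:g}",
                "p_false": 100.0 * np.mean(~correct[m]) if m.any() else float("nan"),
                "n": int(m.sum()),
            }
        )
    return {
        "cl_true_mean": float(true_cl.mean()) if len(true_cl) else float("nan"),
        "cl_true_median": float(np.median(true_cl)) if len(true_cl) else float("nan"),
        "cl_false_mean": float(false_cl.mean()) if len(false_cl) else float("nan"),
        "cl_false_median": float(np.median(false_cl)) if len(false_cl) else float("nan"),
        "cutoff": cutoff,
        "cutoff_accuracy": 100.0 * np.mean(correct[above]) if above.any() else float("nan"),
        "share_above_cutoff": 100.0 * float(above.mean()),
        "misdiagnosis_by_bin": mis,
        "n_true": int(correct.sum()),
        "n_false": int((~correct).sum()),
    }


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------


@dataclass
class WindowDataset:
    """All per-window arrays an experiment needs, computed once."""

    windows: list[WindowSample]
    x_dl: np.ndarray  # resampled classifier input
    labels: np.ndarray  # "AF"/"SR"
    patient_ids: np.ndarray
    burdens: np.ndarray  # ground-truth PAC burden fraction (NaN if unknown)
    features: list  # FeatureVector or None per window
    feature_ok: np.ndarray

    @classmethod
    def from_windows(
        cls, windows: list[WindowSample], dl_config: dlmod.ModelConfig | None = None
    ) -> "WindowDataset":
        x_dl = dlmod.prepare_input(windows, dl_config)
        labels = np.array([w.label for w in windows])
        pids = np.array([w.patient_id for w in windows])
        burdens = np.array(
            [w.burden if w.burden is not None else np.nan for w in windows]
        )
        feats: list = []
        ok = np.zeros(len(windows), dtype=bool)
        for i, w in enumerate(windows):
            try:
                feats.append(bl.extract_features(w))
                ok[i] = True
            except InsufficientBeatsError:
                feats.append(None)
        return cls(windows, x_dl, labels, pids, burdens, feats, ok)

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class RepeatPredictions:
    """Pooled test-set predictions of one model over one repeat's folds."""

    index: np.ndarray  # window indices
    labels: np.ndarray
    pred: np.ndarray
    scores: np.ndarray  # AF score (higher = more AF-like)
    cl: np.ndarray  # confidence level %, NaN for baseline SVMs
    burdens: np.ndarray
    fold: np.ndarray = None  # fold id per window (for per-validation stats)


@dataclass
class ExperimentResult:
    scenario: str
    plan: CvPlan
    predictions: dict = field(default_factory=dict)  # model -> [RepeatPredictions]

    def pooled(self, model: str) -> RepeatPredictions:
        reps = self.predictions[model]
        return RepeatPredictions(
            index=np.concatenate([r.index for r in reps]),
            labels=np.concatenate([r.labels for r in reps]),
            pred=np.concatenate([r.pred for r in reps]),
            scores=np.concatenate([r.scores for r in reps]),
            cl=np.concatenate([r.cl for r in reps]),
            burdens=np.concatenate([r.burdens for r in reps]),
            fold=np.concatenate([r.fold for r in reps]),
        )

    def report(self, model: str) -> dict:
        """Rates averaged over repeats; AUC averaged over per-repeat pooled
        scores; burden table and CL summary on all repeats pooled."""
        reps = self.predictions[model]
        per_rep = [metrics(r.pred, r.labels) for r in reps]
        avg = {
            k: float(np.nanmean([m[k] for m in per_rep]))
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
        }
        aucs = [roc_auc(r.scores, r.labels) for r in reps]
        pooled = self.pooled(model)
        auc, lo, hi = auc_ci_delong(pooled.scores, pooled.labels)
        out = {
            **avg,
            "auc_mean": float(np.mean(aucs)),
            "auc_pooled": auc,
            "auc_ci": (lo, hi),
            "per_repeat": per_rep,
            "burden_specificity": burden_stratified_specificity(
                pooled.pred, pooled.labels, pooled.burdens
            ),
            "n": int(sum(m["n"] for m in per_rep)),
        }
        if np.isfinite(pooled.cl).any():
            out["cl"] = cl_analysis(pooled.cl, pooled.pred == pooled.labels)
        return out


def paired_specificity_test(
    result: "ExperimentResult", model_1: str, model_2: str
) -> tuple[float, float]:
    """Paired t-test of specificity between two models over all fold x repeat
    validations (models share fold assignments, so pairing is valid).

    Returns (t, p) two-sided.
    """
    spec: dict[str, list[float]] = {model_1: [], model_2: []}
    for name in (model_1, model_2):
        for rep in result.predictions[name]:
            for f in np.unique(rep.fold):
                m = (rep.fold == f) & (rep.labels == SR)
                if m.any():
                    spec[name].append(float(np.mean(rep.pred[m] == SR)))
    a, b = np.array(spec[model_1]), np.array(spec[model_2])
    if a.shape != b.shape:
        raise InputError("models were not evaluated on the same validations")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def _plan_for(scenario: str, ds: WindowDataset, k: int, repeats: int, seed: int) -> CvPlan:
    if scenario.upper() == "A":
        return split_scenario_a(ds.patient_ids, k=k, repeats=repeats, seed=seed)
    if scenario.upper() == "B":
        return split_scenario_b(ds.labels, k=k, repeats=repeats, seed=seed)
    raise ParameterError(f"scenario must be 'A' or 'B', got {scenario!r}")


def run_cv(
    ds: WindowDataset,
    models: tuple[str, ...] = MODEL_NAMES,
    scenario: str = "A",
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    dl_config: dlmod.ModelConfig | None = None,
) -> ExperimentResult:
    """Run one scenario end to end for the requested models.

    All models share the same fold assignments within a repeat (so DeLong
    pairing across models is valid on the common windows). Baseline SVMs use
    only windows with usable detected-beat features; the deep classifiers
    consume every window.
    """
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ParameterError(f"unknown models: {sorted(unknown)}")
    plan = _plan_for(scenario, ds, k, repeats, seed)
    base_cfg = dl_config or dlmod.ModelConfig()
    result = ExperimentResult(scenario=plan.scenario, plan=plan)
    for name in models:
        result.predictions[name] = []
    y_int = dlmod.encode_labels(list(ds.labels))

    for r in range(repeats):
        per_model: dict[str, list[RepeatPredictions]] = {m: [] for m in models}
        for f in range(k):
            train_idx, test_idx = plan.train_test(r, f, len(ds))
            for name in models:
                if name in ("cnn1d", "rnn"):
                    fold_seed = int(
                        np.random.SeedSequence(
                            [seed, 0xD, r, f, 0 if name == "cnn1d" else 1]
                        ).generate_state(1)[0]
                        % (2**31)
                    )
                    cfg = dataclasses.replace(base_cfg, arch=name, seed=fold_seed)
                    model = dlmod.build_model(cfg)
                    dlmod.train(model, ds.x_dl[train_idx], y_int[train_idx], cfg)
                    probs = dlmod.predict_proba(model, ds.x_dl[test_idx])
                    scores = probs[:, 0]
                    pred = np.where(probs[:, 0] >= probs[:, 1], AF, SR)
                    cl = 100.0 * probs.max(axis=1)
                    idx_used = test_idx
                else:
                    fset = name.removeprefix("svm_")
                    tr = train_idx[ds.feature_ok[train_idx]]
                    te = test_idx[ds.feature_ok[test_idx]]
                    fx = bl.feature_matrix([ds.features[i] for i in tr], fset)
                    clf = bl.train_svm(fx, ds.labels[tr])
                    fx_te = bl.feature_matrix([ds.features[i] for i in te], fset)
                    dec = clf.decision_function(fx_te)
                    # LinearSVC orders classes alphabetically: AF is class 0,
                    # so a positive decision value means SR.
                    scores = -dec
                    pred = clf.predict(fx_te)
                    cl = np.full(len(te), np.nan)
                    idx_used = te
                per_model[name].append(
                    RepeatPredictions(
                        index=idx_used,
                        labels=ds.labels[idx_used],
                        pred=pred,
                        scores=scores,
                        cl=cl,
                        burdens=ds.burdens[idx_used],
                        fold=np.full(len(idx_used), f),
                    )
                )
        for name in models:
            parts = per_model[name]
            result.predictions[name].append(
                RepeatPredictions(
                    index=np.concatenate([p.index for p in parts]),
                    labels=np.concatenate([p.labels for p in parts]),
                    pred=np.concatenate([p.pred for p in parts]),
                    scores=np.concatenate([p.scores for p in parts]),
                    cl=np.concatenate([p.cl for p in parts]),
                    burdens=np.concatenate([p.burdens for p in parts]),
                    fold=np.concatenate([p.fold for p in parts]),
                )
            )
    return result
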