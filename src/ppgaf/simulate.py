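"""Synthetic PPG cohort generator.

Emulates the study design this package targets: each synthetic patient
contributes a pre-cardioversion recording in atrial fibrillation (AF) and a
post-cardioversion recording in sinus rhythm (SR), with SR recordings
carrying premature atrial complexes (PACs) at a controlled, patient-specific
rate. Every record carries ground-truth beat times and PAC flags so the beat
detector and PAC indicator can be validated against a known truth.

Rhythm models
-------------
AF inter-beat intervals are i.i.d. draws from a truncated lognormal — the
simplest model of an "irregularly irregular" rhythm with no serial
structure. SR intervals follow a low-variance Gaussian jitter around the
mean plus a sinusoidal respiratory modulation (respiratory sinus
arrhythmia). PACs replace a scheduled sinus beat with an early beat whose
coupling interval is a fraction (< 0.85) of the local mean RR, followed by a
fully compensatory pause, so every synthetic PAC is detectable by the 85%
interval rule by construction.

The pulse waveform is a smooth two-component template per beat (systolic
Gaussian peak plus a smaller, delayed dicrotic bump), with pulse amplitude
reduced after short intervals to emulate reduced diastolic filling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import AF, POST_DCC, PRE_DCC, SR, PPGRecord, RRSeries
from .errors import ParameterError

_RESP_FREQ_HZ = 0.25  # respiratory modulation frequency (15 breaths/min)
_MIN_RR = 0.30  # physiological floor on any interval, seconds


@dataclass
class RhythmParams:
    """Generative parameters for one recording.

    Parameters
    ----------
    rhythm : {"AF", "SR"}
    mean_rr : float
        Mean inter-beat interval, seconds.
    rr_sd : float
        Interval standard deviation, seconds. For AF the implied coefficient
        of variation ``rr_sd / mean_rr`` must be >= 0.15.
    pac_rate : float
        Expected PACs per minute (SR only; must be 0 for AF).
    coupling_frac : float or None
        PAC prematurity as a fraction of the local mean RR. When ``None``
        each PAC draws its coupling fraction uniformly from [0.55, 0.80].
    compensatory_frac : float
        Coupling interval plus post-PAC pause, as a multiple of the local
        mean RR. 2.0 is a fully compensatory pause (the following sinus beat
        stays on schedule).
    resp_mod_depth : float
        Fractional depth of the sinusoidal respiratory RR modulation (SR).
    noise_sd : float
        Additive Gaussian noise on the rendered signal, in signal units
        (the clean pulse has unit nominal amplitude).
    fs : float
        Sampling rate, Hz (>= 20 so the pulse template is representable).
    duration : float
        Recording length, seconds.
    seed : int
        Seed for all randomness in this recording.
    amp_slope : float
        Pulse-amplitude sensitivity to the preceding interval: amplitude is
        ``1 + amp_slope * (rr_prev - mean_rr) / mean_rr`` (clipped).
    sys_width_frac, dicrotic_amp, dicrotic_delay_frac, dicrotic_width_frac :
        Pulse-template morphology, as fractions of the beat interval
        (widths/delay) and of the systolic amplitude (dicrotic_amp).
    """

    rhythm: str = SR
    mean_rr: float = 0.9
    rr_sd: float = 0.03
    pac_rate: float = 0.0
    coupling_frac: float | None = None
    compensatory_frac: float = 2.0
    resp_mod_depth: float = 0.04
    noise_sd: float = 0.05
    fs: float = 100.0
    duration: float = 900.0
    seed: int = 0
    amp_slope: float = 0.8
    sys_width_frac: float = 0.10
    dicrotic_amp: float = 0.35
    dicrotic_delay_frac: float = 0.35
    dicrotic_width_frac: float = 0.16

    def __post_init__(self) -> None:
        if self.rhythm not in (AF, SR):
            raise ParameterError(f"rhythm must be 'AF' or 'SR', got {self.rhythm!r}")
        if self.mean_rr <= 0:
            raise ParameterError("mean_rr must be > 0")
        if self.rr_sd < 0:
            raise ParameterError("rr_sd must be >= 0")
        if self.rhythm == AF and self.rr_sd / self.mean_rr < 0.15:
            raise ParameterError("rr_sd: AF requires coefficient of variation >= 0.15")
        if self.rhythm == AF and self.pac_rate != 0:
            raise ParameterError("pac_rate: PACs are only defined against SR")
        if self.pac_rate < 0:
            raise ParameterError("pac_rate must be >= 0")
        if self.coupling_frac is not None and not 0 < self.coupling_frac < 0.85:
            raise ParameterError("coupling_frac must lie in (0, 0.85)")
        if self.compensatory_frac < 1.0:
            raise ParameterError("compensatory_frac must be >= 1.0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.fs < 20:
            raise ParameterError("fs must be >= 20 Hz to represent the pulse template")

    def replace(self, **kw) -> "RhythmParams":
        return dataclasses.replace(self, **kw)


def _rng(params: RhythmParams, stream: int) -> np.random.Generator:
    # distinct, reproducible stream per operation
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), stream]))


def simulate_rr(params: RhythmParams, rng: np.random.Generator | None = None) -> RRSeries:
    """Draw a beat-time series for one recording.

    AF intervals are i.i.d. truncated lognormal with mean ``mean_rr`` and
    coefficient of variation ``rr_sd / mean_rr``; SR intervals are Gaussian
    jitter plus respiratory modulation. Beats are generated until the
    recording duration is covered; every interval exceeds 0.25 s.
    """
    if rng is None:
        rng = _rng(params, 1)
    n_est = int(np.ceil(params.duration / params.mean_rr)) + 16

    if params.rhythm == AF:
        cv = params.rr_sd / params.mean_rr
        sigma2 = np.log1p(cv**2)
        mu = np.log(params.mean_rr) - sigma2 / 2.0
        lo, hi = max(_MIN_RR, 0.25 * params.mean_rr), 2.5 * params.mean_rr
        intervals = np.empty(0)
        while intervals.sum() < params.duration:
            draw = rng.lognormal(mu, np.sqrt(sigma2), n_est)
            draw = draw[(draw > lo) & (draw < hi)]
            intervals = np.concatenate([intervals, draw])
        k = int(np.searchsorted(np.cumsum(intervals), params.duration)) + 1
        intervals = intervals[:k]
        beat_times = np.concatenate([[0.0], np.cumsum(intervals)])
        beat_times += 0.5 * params.mean_rr  # start offset
        return RRSeries(beat_times=beat_times)

    # SR: sequential so modulation follows elapsed time
    times = [0.5 * params.mean_rr]
    while times[-1] < params.duration + 0.5 * params.mean_rr:
        t = times[-1]
        rr = params.mean_rr * (
            1.0 + params.resp_mod_depth * np.sin(2 * np.pi * _RESP_FREQ_HZ * t)
        )
        if params.rr_sd > 0:
            rr += rng.normal(0.0, params.rr_sd)
        times.append(t + max(rr, _MIN_RR))
    return RRSeries(beat_times=np.asarray(times))


def insert_pacs(
    rr: RRSeries, params: RhythmParams, rng: np.random.Generator | None = None
) -> RRSeries:
    """Replace randomly chosen sinus beats with premature atrial complexes.

    Each PAC moves a scheduled sinus beat earlier so that its coupling
    interval is ``coupling_frac``  x  the local mean RR (drawn uniformly from
    [0.55, 0.80] when ``coupling_frac`` is None), followed by a compensatory
    pause. With the default fully compensatory pause the subsequent sinus
    beats keep their original times, so the total duration is preserved
    exactly and every PAC's coupling interval sits below 85% of the window
    mean RR — guaranteeing detectability by the interval rule.
    """
    if params.rhythm == AF:
        raise ParameterError("pac_rate: PACs are only defined against SR")
    if params.pac_rate == 0:
        return RRSeries(beat_times=rr.beat_times.copy())
    if rng is None:
        rng = _rng(params, 2)

    beat_times = rr.beat_times.copy()
    n = len(beat_times)
    flags = np.zeros(n, dtype=bool)
    n_target = rng.poisson(params.pac_rate * params.duration / 60.0)
    if n_target == 0 or n < 6:
        return RRSeries(beat_times=beat_times, pac_flags=flags)

    # candidate beats to convert; keep >=2 beats between PACs
    candidates = rng.permutation(np.arange(2, n - 2))
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for j in candidates:
        if len(chosen) >= n_target:
            break
        if taken[max(0, j - 2) : j + 3].any():
            continue
        chosen.append(int(j))
        taken[j] = True

    intervals = np.diff(rr.beat_times)
    for j in sorted(chosen):
        lo = max(0, j - 6)
        local_mean = float(np.mean(intervals[lo : j + 5]))
        frac = (
            params.coupling_frac
            if params.coupling_frac is not None
            else rng.uniform(0.55, 0.80)
        )
        coupling = frac * local_mean
        new_t = beat_times[j - 1] + coupling
        if new_t <= beat_times[j - 1] + _MIN_RR - 0.05 or new_t >= beat_times[j + 1]:
            continue
        beat_times[j] = new_t
        flags[j] = True
        if params.compensatory_frac != 2.0:
            # displace only the following beat; later beats keep their times
            t_next = beat_times[j - 1] + params.compensatory_frac * local_mean
            upper = beat_times[j + 2] if j + 2 < n else np.inf
            if beat_times[j] < t_next < upper:
                beat_times[j + 1] = t_next
    order_ok = np.all(np.diff(beat_times) > 0)
    if not order_ok:  # pragma: no cover - guarded by construction
        keep = np.concatenate([[True], np.diff(beat_times) > 0])
        beat_times, flags = beat_times[keep], flags[keep]
    return RRSeries(beat_times=beat_times, pac_flags=flags)


def render_ppg(
    rr: RRSeries,
    params: RhythmParams,
    patient_id: str = "P000",
    rng: np.random.Generator | None = None,
) -> PPGRecord:
    """Render a beat series into a sampled PPG waveform.

    One pulse per beat: a systolic Gaussian peak centred on the beat time
    plus a delayed dicrotic bump, both scaled to the surrounding interval so
    pulses never collide. Pulse amplitude falls after short preceding
    intervals (reduced ventricular filling), which is what makes AF and
    post-PAC pulses look attenuated. Additive white Gaussian noise at
    ``noise_sd`` completes the record.
    """
    if params.fs < 20:
        raise ParameterError("fs must be >= 20 Hz to represent the pulse template")
    if rng is None:
        rng = _rng(params, 3)
    n = int(round(params.fs * params.duration))
    signal = np.zeros(n)
    bt = rr.beat_times
    if len(bt) < 2:
        raise ParameterError("duration: too short to contain two beats")
    intervals = np.diff(bt)
    mean_rr = float(np.mean(intervals))
    prev = np.concatenate([[mean_rr], intervals])  # interval preceding each beat
    nxt = np.concatenate([intervals, [mean_rr]])  # interval following each beat

    for i, t0 in enumerate(bt):
        ref = float(np.clip(min(nxt[i], 1.3 * mean_rr), _MIN_RR, 1.6))
        amp = float(np.clip(1.0 + params.amp_slope * (prev[i] - mean_rr) / mean_rr, 0.3, 1.8))
        w1 = params.sys_width_frac * ref
        w2 = params.dicrotic_width_frac * ref
        delay = params.dicrotic_delay_frac * ref
        # 6-sigma support keeps truncation error below 1e-7 of the amplitude
        lo = max(0, int((t0 - 6 * w1) * params.fs))
        hi = min(n, int((t0 + delay + 6 * w2) * params.fs) + 1)
        if hi <= lo:
            continue
        t = np.arange(lo, hi) / params.fs
        pulse = np.exp(-0.5 * ((t - t0) / w1) ** 2)
        pulse += params.dicrotic_amp * np.exp(-0.5 * ((t - t0 - delay) / w2) ** 2)
        signal[lo:hi] += amp * pulse

    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, n)
    phase = PRE_DCC if params.rhythm == AF else POST_DCC
    return PPGRecord(
        samples=signal,
        fs=params.fs,
        patient_id=patient_id,
        phase=phase,
        label=params.rhythm,
        beat_times=bt,
        pac_flags=rr.pac_flags,
    )


def simulate_record(params: RhythmParams, patient_id: str = "P000") -> PPGRecord:
    """Full single-recording pipeline: beat series -> PACs (SR) -> waveform."""
    rr = simulate_rr(params)
    if params.rhythm == SR and params.pac_rate > 0:
        rr = insert_pacs(rr, params)
    return render_ppg(rr, params, patient_id=patient_id)


@dataclass
class CohortConfig:
    """Per-patient parameter ranges for :func:`generate_cohort`.

    Ranges are uniform unless noted. The PAC-rate mixture reflects the
    clinical picture after cardioversion: many patients with no ectopy, some
    with occasional PACs, and a minority with frequent PACs up to
    bigeminy-like runs — calibrated so roughly 30% of SR windows contain at
    least one PAC.
    """

    duration: float = 900.0
    fs: float = 100.0
    sr_mean_rr: tuple[float, float] = (0.70, 1.05)
    af_mean_rr: tuple[float, float] = (0.50, 0.90)
    af_cv: tuple[float, float] = (0.18, 0.30)
    sr_rr_sd: tuple[float, float] = (0.015, 0.040)
    resp_mod_depth: tuple[float, float] = (0.02, 0.06)
    noise_sd: tuple[float, float] = (0.03, 0.08)
    amp_slope: tuple[float, float] = (0.5, 1.1)
    sys_width_frac: tuple[float, float] = (0.08, 0.12)
    dicrotic_amp: tuple[float, float] = (0.25, 0.45)
    dicrotic_delay_frac: tuple[float, float] = (0.30, 0.42)
    dicrotic_width_frac: tuple[float, float] = (0.13, 0.19)
    # PAC-rate mixture: (probability, (lo, hi) PACs/min)
    pac_mixture: tuple[tuple[float, tuple[float, float]], ...] = (
        (0.58, (0.0, 0.0)),
        (0.14, (0.3, 1.5)),
        (0.14, (2.0, 5.0)),
        (0.14, (8.0, 16.0)),
    )


def generate_cohort(
    n_patients: int,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> list[PPGRecord]:
    """Generate a paired AF/SR cohort of ``2 * n_patients`` records.

    Each patient draws individual heart rates, variability, PAC rate, noise
    level and pulse morphology, so patients genuinely differ — which is what
    makes patient-wise cross-validation harder than sample-wise. Deterministic
    under a fixed seed.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    cfg = config or CohortConfig()
    records: list[PPGRecord] = []
    ss = np.random.SeedSequence(seed)
    for p, child in enumerate(ss.spawn(n_patients)):
        rng = np.random.default_rng(child)
        pid = f"P{p:03d}"
        u = rng.uniform
        morph = dict(
            amp_slope=u(*cfg.amp_slope),
            sys_width_frac=u(*cfg.sys_width_frac),
            dicrotic_amp=u(*cfg.dicrotic_amp),
            dicrotic_delay_frac=u(*cfg.dicrotic_delay_frac),
            dicrotic_width_frac=u(*cfg.dicrotic_width_frac),
        )
        noise = u(*cfg.noise_sd)
        seeds = rng.integers(0, 2**31 - 1, size=2)

        af_rr = u(*cfg.af_mean_rr)
        af = RhythmParams(
            rhythm=AF,
            mean_rr=af_rr,
            rr_sd=u(*cfg.af_cv) * af_rr,
            noise_sd=noise,
            fs=cfg.fs,
            duration=cfg.duration,
            seed=int(seeds[0]),
            **morph,
        )
        records.append(simulate_record(af, patient_id=pid))

        probs = np.array([w for w, _ in cfg.pac_mixture])
        comp = rng.choice(len(probs), p=probs / probs.sum())
        lo, hi = cfg.pac_mixture[comp][1]
        pac_rate = float(u(lo, hi)) if hi > lo else float(lo)
        sr = RhythmParams(
            rhythm=SR,
            mean_rr=u(*cfg.sr_mean_rr),
            rr_sd=u(*cfg.sr_rr_sd),
            pac_rate=pac_rate,
            resp_mod_depth=u(*cfg.resp_mod_depth),
            noise_sd=noise,
            fs=cfg.fs,
            duration=cfg.duration,
            seed=int(seeds[1]),
            **morph,
        )
        records.append(simulate_record(sr, patient_id=pid))
    return records
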