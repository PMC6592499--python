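import numpy as np
import pytest

from ppgaf.core import AF, SR
from ppgaf.errors import ParameterError
from ppgaf.simulate import (
    CohortConfig,
    RhythmParams,
    generate_cohort,
    insert_pacs,
    render_ppg,
    simulate_record,
    simulate_rr,
)


class TestRhythmParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"mean_rr": -1.0},
            {"rhythm": "AF", "rr_sd": 0.05, "mean_rr": 1.0},  # CV < 0.15
            {"rhythm": "AF", "pac_rate": 2.0, "rr_sd": 0.3},
            {"coupling_frac": 0.9},
            {"compensatory_frac": 0.5},
            {"duration": 0.0},
            {"fs": 10.0},
            {"rhythm": "VT"},
        ],
    )
    def test_invalid_params_rejected_with_field_name(self, kw):
        with pytest.raises(ParameterError):
            RhythmParams(**kw)


class TestSimulateRr:
    def test_zero_variance_sr_gives_constant_intervals(self):
        p = RhythmParams(rhythm=SR, mean_rr=1.0, rr_sd=0.0, resp_mod_depth=0.0, duration=120)
        rr = simulate_rr(p)
        assert np.allclose(rr.intervals, 1.0)

    def test_af_sample_cv_matches_configured_cv(self):
        # Monte-Carlo check of the interval distribution's second moment
        p = RhythmParams(rhythm=AF, mean_rr=0.8, rr_sd=0.2, duration=900, seed=2)
        rr = simulate_rr(p)
        assert rr.n_beats >= 500
        cv = rr.intervals.std() / rr.intervals.mean()
        assert abs(cv - 0.25) / 0.25 < 0.20

    def test_af_intervals_serially_independent(self):
        p = RhythmParams(rhythm=AF, mean_rr=0.8, rr_sd=0.2, duration=900, seed=3)
        iv = simulate_rr(p).intervals
        r1 = np.corrcoef(iv[:-1], iv[1:])[0, 1]
        assert abs(r1) < 0.1

    def test_beat_count_tracks_duration_over_mean_rr(self):
        p = RhythmParams(rhythm=SR, mean_rr=1.0, duration=900, seed=4)
        rr = simulate_rr(p)
        assert rr.n_beats == pytest.approx(900, rel=0.05)

    def test_intervals_cover_duration_and_respect_floor(self):
        for rhythm, sd in ((AF, 0.25), (SR, 0.05)):
            p = RhythmParams(rhythm=rhythm, mean_rr=0.7, rr_sd=sd, duration=300, seed=5)
            rr = simulate_rr(p)
            assert rr.intervals.sum() >= 300 - 0.7
            assert rr.intervals.min() > 0.25


class TestInsertPacs:
    def test_zero_rate_is_identity(self):
        p = RhythmParams(rhythm=SR, pac_rate=0.0, duration=120)
        rr = simulate_rr(p)
        out = insert_pacs(rr, p)
        assert np.array_equal(out.beat_times, rr.beat_times)
        assert out.pac_flags.sum() == 0

    def test_single_pac_coupling_interval_by_construction(self):
        p = RhythmParams(
            rhythm=SR, mean_rr=1.0, rr_sd=0.0, resp_mod_depth=0.0,
            pac_rate=0.1, coupling_frac=0.6, duration=600, seed=6,
        )
        rr = insert_pacs(simulate_rr(p), p)
        flagged = np.flatnonzero(rr.pac_flags)
        assert len(flagged) >= 1
        pre = rr.intervals[flagged - 1]
        assert np.allclose(pre, 0.6, atol=1e-9)

    def test_pac_count_within_poisson_noise(self):
        p = RhythmParams(rhythm=SR, mean_rr=1.0, rr_sd=0.0, resp_mod_depth=0.0,
                         pac_rate=6.0, duration=900, seed=7)
        rr = insert_pacs(simulate_rr(p), p)
        n = rr.pac_flags.sum()
        assert abs(n - 90) <= 3 * np.sqrt(90)

    def test_duration_preserved_with_fully_compensatory_pause(self):
        p = RhythmParams(rhythm=SR, mean_rr=0.9, rr_sd=0.02, pac_rate=8.0,
                         duration=600, seed=8)
        rr0 = simulate_rr(p)
        rr = insert_pacs(rr0, p)
        assert abs(rr.beat_times[-1] - rr0.beat_times[-1]) <= p.mean_rr

    def test_every_pac_detectable_by_85_percent_rule(self):
        # construction guarantee: coupling < 0.85 x local mean
        p = RhythmParams(rhythm=SR, mean_rr=0.8, rr_sd=0.02, pac_rate=6.0,
                         duration=600, seed=9)
        rr = insert_pacs(simulate_rr(p), p)
        flagged = np.flatnonzero(rr.pac_flags)
        mean_rr = rr.intervals.mean()
        assert (rr.intervals[flagged - 1] < 0.85 * mean_rr).all()

    def test_pacs_on_af_rejected(self):
        p_sr = RhythmParams(rhythm=SR, duration=60)
        rr = simulate_rr(p_sr)
        p_af = RhythmParams(rhythm=AF, rr_sd=0.2, duration=60)
        with pytest.raises(ParameterError):
            insert_pacs(rr, p_af)


class TestRenderPpg:
    def test_clean_constant_rr_is_periodic(self):
        p = RhythmParams(rhythm=SR, mean_rr=1.0, rr_sd=0.0, resp_mod_depth=0.0,
                         noise_sd=0.0, duration=30, fs=100)
        rec = render_ppg(simulate_rr(p), p)
        period = int(p.mean_rr * p.fs)
        x = rec.samples
        # compare away from both record edges (truncated edge pulses)
        assert np.allclose(x[2 * period : 18 * period], x[3 * period : 19 * period], atol=1e-6)

    def test_peak_count_matches_beat_count_on_clean_signal(self):
        from scipy.signal import find_peaks

        p = RhythmParams(rhythm=SR, mean_rr=0.9, rr_sd=0.02, noise_sd=0.0,
                         duration=120, seed=10)
        rr = simulate_rr(p)
        rec = render_ppg(rr, p)
        peaks, _ = find_peaks(rec.samples, height=0.5 * rec.samples.max(), distance=25)
        in_range = (rr.beat_times > 0.2) & (rr.beat_times < rec.duration - 0.2)
        assert abs(len(peaks) - in_range.sum()) <= 2

    def test_noise_scales_residual_sd(self):
        p0 = RhythmParams(rhythm=SR, noise_sd=0.0, duration=60, seed=11)
        clean = render_ppg(simulate_rr(p0), p0).samples
        sds = []
        for nsd in (0.05, 0.10):
            p = p0.replace(noise_sd=nsd)
            noisy = render_ppg(simulate_rr(p), p).samples
            sds.append((noisy - clean).std())
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.1)

    def test_rendered_length_matches_duration(self):
        p = RhythmParams(rhythm=SR, duration=123.0, fs=100)
        rec = simulate_record(p)
        assert len(rec.samples) == round(p.fs * p.duration)


class TestGenerateCohort:
    def test_pair_per_patient_with_labels_and_phases(self):
        recs = generate_cohort(3, CohortConfig(duration=60), seed=1)
        assert len(recs) == 6
        by_pid = {}
        for r in recs:
            by_pid.setdefault(r.patient_id, []).append((r.phase, r.label))
        assert all(
            sorted(v) == [("post_dcc", "SR"), ("pre_dcc", "AF")] for v in by_pid.values()
        )

    def test_same_seed_bit_identical(self):
        a = generate_cohort(2, CohortConfig(duration=60), seed=5)
        b = generate_cohort(2, CohortConfig(duration=60), seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)
            assert np.array_equal(ra.beat_times, rb.beat_times)

    def test_different_seeds_differ(self):
        a = generate_cohort(1, CohortConfig(duration=60), seed=1)
        b = generate_cohort(1, CohortConfig(duration=60), seed=2)
        assert not np.array_equal(a[0].samples, b[0].samples)

    def test_invalid_patient_count(self):
        with pytest.raises(ParameterError):
            generate_cohort(0)
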