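"""The organization-graded generator and the AV-node concealed-conduction
model: determinism, degenerate limits, moment targets, conservation, and
the monotone links from disorganization to entropy and to ventricular
irregularity."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from aforg import (
    ActivationTrain,
    AVNodeSpec,
    OrganizationSpec,
    conduct_av_node,
    generate_atrial_train,
    generate_cohort,
    render_ecg,
    render_electrogram,
    rri_metrics,
    segment_windows,
    to_rri,
    window_sampen,
    window_shen,
)
from aforg.synthetic import _rng
from conftest import FS, make_egm_recording


class TestActivationTrain:
    def test_theta_zero_is_exactly_periodic(self):
        train = generate_atrial_train(OrganizationSpec(theta=0.0), 50.0)
        intervals = np.diff(np.concatenate([[0.0], train.times_ms]))
        assert np.all(intervals == 170.0)
        assert len(train) == 294  # floor(50000 / 170)

    def test_times_strictly_increasing_within_bounds(self):
        spec = OrganizationSpec(theta=0.9, seed=4)
        train = generate_atrial_train(spec, 30.0)
        assert np.all(np.diff(train.times_ms) > 0)
        assert train.times_ms[0] > 0 and train.times_ms[-1] <= 30_000.0

    def test_interval_cv_matches_target(self):
        """At theta = 0.8 the sample CV of ~10k intervals is within 5 %
        of theta * cycle_cv_max (moments of the sampling distribution)."""
        spec = OrganizationSpec(theta=0.8, seed=1)
        train = generate_atrial_train(spec, 10_000 * 0.170, rng=_rng(1))
        iv = np.diff(np.concatenate([[0.0], train.times_ms]))
        target = 0.8 * spec.cycle_cv_max
        assert iv.std() / iv.mean() == pytest.approx(target, rel=0.05)
        assert iv.min() >= spec.floor_ms

    def test_validation_names_offending_field(self):
        with pytest.raises(ValueError, match="theta"):
            OrganizationSpec(theta=1.5)
        with pytest.raises(ValueError, match="mean_cycle_ms"):
            OrganizationSpec(mean_cycle_ms=-10)
        with pytest.raises(ValueError, match="noise_sd"):
            OrganizationSpec(noise_sd=float("nan"))
        with pytest.raises(ValueError, match="duration_s"):
            generate_atrial_train(OrganizationSpec(), -1.0)


class TestElectrogramRenderer:
    def test_theta_zero_noiseless_is_periodic(self):
        spec = OrganizationSpec(theta=0.0, noise_sd=0.0)
        train = generate_atrial_train(spec, 10.0)
        trace = render_electrogram(train, spec, fs=1000.0)
        # cycle = 170 samples at 1 kHz; interior cycles repeat exactly
        assert np.array_equal(trace[340:510], trace[510:680])
        assert np.array_equal(trace[510:680], trace[680:850])

    def test_empty_train_noiseless_is_all_zero(self):
        train = ActivationTrain(times_ms=np.array([]), duration_ms=5000.0)
        trace = render_electrogram(train, OrganizationSpec(theta=0.0, noise_sd=0.0), fs=500.0)
        assert trace.shape == (2500,) and not trace.any()

    def test_empty_train_with_noise_is_noise_only(self):
        train = ActivationTrain(times_ms=np.array([]), duration_ms=2000.0)
        trace = render_electrogram(
            train, OrganizationSpec(theta=0.5, noise_sd=0.1), fs=250.0,
            rng=np.random.default_rng(0),
        )
        assert trace.std() == pytest.approx(0.1, rel=0.2)

    def test_low_fs_rejected(self):
        train = generate_atrial_train(OrganizationSpec(theta=0.0), 2.0)
        with pytest.raises(ValueError, match="fs"):
            render_electrogram(train, OrganizationSpec(), fs=100.0)

    def test_organized_trace_has_lower_entropy_than_disorganized(self):
        """theta = 0 window scores below theta = 1 on both measures."""
        rec0 = make_egm_recording(0.0, (101, 0))
        rec1 = make_egm_recording(1.0, (101, 0))
        w0 = segment_windows(rec0)[0]
        w1 = segment_windows(rec1)[0]
        assert window_shen(w0, "CS1-2") < window_shen(w1, "CS1-2")
        assert window_sampen(w0, "CS1-2") < window_sampen(w1, "CS1-2")


class TestDeterminism:
    def test_identical_seeds_reproduce_everything(self):
        spec = OrganizationSpec(theta=0.6, seed=9)
        t1 = generate_atrial_train(spec, 20.0)
        t2 = generate_atrial_train(spec, 20.0)
        assert np.array_equal(t1.times_ms, t2.times_ms)
        e1 = render_electrogram(t1, spec, fs=250.0)
        e2 = render_electrogram(t2, spec, fs=250.0)
        assert np.array_equal(e1, e2)
        av = AVNodeSpec(seed=3)
        r1 = conduct_av_node(t1, av)
        r2 = conduct_av_node(t2, av)
        assert np.array_equal(r1.beat_times_ms, r2.beat_times_ms)

    def test_cohort_reproducible_and_windows_regenerable(self):
        a = generate_cohort(2, effect=0.2, seed=5, n_windows=1, fs=250.0,
                            include_ecg=False)
        b = generate_cohort(2, effect=0.2, seed=5, n_windows=1, fs=250.0,
                            include_ecg=False)
        for pa, pb in zip(a, b):
            assert pa.theta_pre == pb.theta_pre
            for ra, rb in zip(pa.recordings, pb.recordings):
                for ch in ra.signals:
                    assert np.array_equal(ra.signals[ch], rb.signals[ch])


class TestAVNode:
    def test_conservation_of_impulses(self):
        spec = OrganizationSpec(theta=0.8, seed=2)
        train = generate_atrial_train(spec, 60.0)
        res = conduct_av_node(train, AVNodeSpec())
        assert res.n_conducted + res.n_blocked == len(train)
        assert res.n_conducted == len(res.beat_times_ms)

    def test_regular_train_no_jitter_is_eventually_periodic(self):
        train = generate_atrial_train(OrganizationSpec(theta=0.0), 60.0)
        res = conduct_av_node(train, AVNodeSpec(refractory_jitter_sd_ms=0.0))
        rr = np.diff(res.beat_times_ms)
        assert len(np.unique(rr[5:])) == 1
        m = rri_metrics(to_rri(res.beat_times_ms[5:]))
        assert m.pnn50 == 0.0

    def test_single_impulse_one_beat_no_intervals(self):
        train = ActivationTrain(times_ms=np.array([100.0]), duration_ms=1000.0)
        res = conduct_av_node(train, AVNodeSpec(refractory_jitter_sd_ms=0.0))
        assert len(res.beat_times_ms) == 1
        assert res.beat_times_ms[0] == 100.0 + 60.0
        assert res.rr_intervals_ms.size == 0

    def test_empty_train_rejected(self):
        empty = ActivationTrain(times_ms=np.array([]), duration_ms=100.0)
        with pytest.raises(ValueError):
            conduct_av_node(empty, AVNodeSpec())

    def test_base_refractory_must_exceed_delay(self):
        with pytest.raises(ValueError, match="base_refractory_ms"):
            AVNodeSpec(base_refractory_ms=50.0, conduction_delay_ms=60.0)

    def test_ventricular_irregularity_increases_with_disorganization(self):
        """Mean normalized SD RRI is strictly increasing over the theta
        grid (20 seeds per level, 60 s trains); pNN50 rank-correlates."""
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        av = AVNodeSpec()
        nsd_means, pnn_means = [], []
        for ti, th in enumerate(levels):
            nsd, pnn = [], []
            for s in range(20):
                spec = OrganizationSpec(theta=th)
                train = generate_atrial_train(spec, 60.0, rng=_rng(21, ti, s, 0))
                res = conduct_av_node(train, av, rng=_rng(21, ti, s, 1))
                m = rri_metrics(to_rri(res.beat_times_ms))
                nsd.append(m.norm_sd_rri)
                pnn.append(m.pnn50)
            nsd_means.append(np.mean(nsd))
            pnn_means.append(np.mean(pnn))
        assert np.all(np.diff(nsd_means) > 0)
        assert spearmanr(levels, pnn_means).statistic > 0.99


class TestECGRenderer:
    def test_r_peak_lands_on_beat_time(self):
        beats = np.array([500.0, 1300.0, 2100.0])
        trace = render_ecg(beats, 3.0, fs=1000.0, noise_sd=0.0)
        for b in beats:
            peak = np.argmax(trace[int(b) - 50 : int(b) + 50]) + int(b) - 50
            assert abs(peak - b) <= 1

    def test_empty_beats_is_flat_noise(self):
        trace = render_ecg(np.array([]), 2.0, fs=250.0, noise_sd=0.0)
        assert not trace.any()


class TestMonotoneOrganizationEntropy:
    def test_spearman_of_theta_vs_mean_entropy(self):
        """Over a 6-level theta grid with 20 windows per level, the rank
        correlation of theta with mean SampEn and mean ShEn is >= 0.9."""
        thetas = np.linspace(0.0, 1.0, 6)
        se_means, sh_means = [], []
        for ti, th in enumerate(thetas):
            se, sh = [], []
            for w in range(20):
                rec = make_egm_recording(float(th), (9, ti, w))
                win = segment_windows(rec)[0]
                se.append(window_sampen(win, "CS1-2"))
                sh.append(window_shen(win, "CS1-2"))
            se_means.append(np.mean(se))
            sh_means.append(np.mean(sh))
        assert spearmanr(thetas, se_means).statistic >= 0.9
        assert spearmanr(thetas, sh_means).statistic >= 0.9


class TestCohortStructure:
    def test_single_patient_shapes(self):
        (p,) = generate_cohort(1, effect=0.2, seed=1, n_windows=2, fs=250.0)
        assert 0.0 <= p.theta_post <= p.theta_pre <= 1.0
        assert 0.0 <= p.pvi_completion <= 1.0
        assert 1 <= len(p.recordings) <= 2
        for rec in p.recordings:
            assert rec.duration_s == 100.0
            assert len(segment_windows(rec)) == 2
            assert set(rec.signals) >= {"CS1-2", "CS3-4", "CS5-6", "CS7-8", "CS9-10"}
            assert rec.beat_times_ms is not None

    def test_incomplete_patients_have_pre_only(self):
        cohort = generate_cohort(30, effect=0.2, seed=7, n_windows=1, fs=250.0,
                                 include_ecg=False)
        for p in cohort:
            phases = {r.phase for r in p.recordings}
            if p.pvi_completion < 0.70:
                assert phases == {"pre"}
            else:
                assert phases == {"pre", "post"}
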