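"""The five classifiers: rule examples, oracles, and structural invariants."""

import numpy as np
import pytest

from conftest import (
    RATE,
    axis_rotation,
    labels,
    make_speed_kin,
    raised_cosine_speed,
    yaw_trace,
)
from headmov.classifiers import (
    BmatConfig,
    CwConfig,
    DizcoConfig,
    MovementEvent,
    SvtConfig,
    TreeConfig,
    annotate_events,
    bmat_classify,
    chen_walton_classify,
    dizco_classify,
    events_to_labels,
    labels_to_events,
    prune_short_intervals,
    svt_classify,
    tree_classify,
    tree_cv_accuracy,
    tree_train,
)
from headmov.kinematics import OrientationTrace, compute_kinematics


class TestBmat:
    def _baseline(self, rng, n=500):
        return rng.normal(0.0, 1.0, size=(n, 3))

    def test_outlying_sample_is_moving(self):
        # normalized radius for (10,0,0) with unit sigma and n=2 is ~5 > 1
        rng = np.random.default_rng(0)
        baseline = self._baseline(rng)
        kin = make_speed_kin(np.zeros(3))
        kin.vel_xyz = np.array([[10.0, 0, 0], [0, 0, 0], [10.0, 10.0, 10.0]])
        out = bmat_classify(kin, baseline, BmatConfig(n_sd=2.0))
        # oracle: evaluate the ellipse inequality directly
        mu, sd = baseline.mean(0), baseline.std(0)
        expected = [
            np.sum(((v - mu) / (2.0 * sd)) ** 2) > 1 for v in kin.vel_xyz
        ]
        assert out.moving.tolist() == expected
        assert out.moving[0] and out.moving[2]

    def test_baseline_mean_is_stationary(self):
        rng = np.random.default_rng(1)
        baseline = self._baseline(rng)
        kin = make_speed_kin(np.zeros(1))
        kin.vel_xyz = baseline.mean(0, keepdims=True)
        for n_sd in (0.2, 1.0, 4.0):
            assert not bmat_classify(kin, baseline, BmatConfig(n_sd=n_sd)).moving[0]

    def test_huge_threshold_labels_nothing(self):
        rng = np.random.default_rng(2)
        kin = make_speed_kin(np.zeros(100))
        kin.vel_xyz = rng.normal(0, 50, (100, 3))
        out = bmat_classify(kin, self._baseline(rng), BmatConfig(n_sd=1e6))
        assert not out.moving.any()

    def test_zero_variance_baseline_rejected(self):
        kin = make_speed_kin(np.zeros(10))
        with pytest.raises(ValueError, match="variance"):
            bmat_classify(kin, np.zeros((50, 3)), BmatConfig())

    def test_moving_sets_nest_as_threshold_grows(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            baseline = rng.normal(0, rng.uniform(0.5, 2), (100, 3))
            kin = make_speed_kin(np.zeros(200))
            kin.vel_xyz = rng.normal(0, 5, (200, 3))
            prev = None
            for n_sd in (0.5, 1.0, 2.0, 4.0):
                cur = bmat_classify(kin, baseline, BmatConfig(n_sd=n_sd)).moving
                if prev is not None:
                    assert not (cur & ~prev).any()  # subset of looser threshold
                prev = cur


class TestSvt:
    def test_single_bump_bounds_match_analytic_zero_crossings(self):
        # bump peaking at 30 deg/s over 0.5 s support; threshold 18.41 deg/s
        speed = raised_cosine_speed(peak=30.0, duration_s=0.5)
        kin = make_speed_kin(speed)
        cfg = SvtConfig(speed_threshold=18.41, savgol_window_ms=33, savgol_polyorder=2)
        events = svt_classify(kin, cfg)
        assert len(events) == 1
        onset_true = 0.5  # pad length
        offset_true = 1.0
        dt = 1 / RATE
        assert abs(events[0].onset - onset_true) <= dt + 1e-9
        assert abs(events[0].offset - offset_true) <= dt + 1e-9

    def test_silent_series_has_no_events(self):
        assert svt_classify(make_speed_kin(np.zeros(300)), SvtConfig()) == []

    def test_two_bumps_with_subthreshold_valley_yield_two_events(self):
        bump = raised_cosine_speed(peak=30.0, duration_s=0.4, pad_s=0.3)
        speed = np.concatenate([bump, bump])
        cfg = SvtConfig(speed_threshold=15.0, savgol_window_ms=33, savgol_polyorder=2)
        events = svt_classify(make_speed_kin(speed), cfg)
        assert len(events) == 2
        assert events[0].offset <= events[1].onset

    def test_peak_above_threshold_and_inside_event(self):
        rng = np.random.default_rng(4)
        speed = np.abs(
            np.convolve(rng.normal(0, 30, 2000), np.ones(9) / 9, mode="same")
        )
        cfg = SvtConfig(speed_threshold=20.0)
        from headmov.kinematics import odd_window_samples, savgol_smooth

        kin = make_speed_kin(speed)
        events = svt_classify(kin, cfg)
        smoothed = savgol_smooth(
            speed, odd_window_samples(cfg.savgol_window_ms, RATE), cfg.savgol_polyorder
        )
        for e in events:
            inside = (kin.timestamps >= e.onset) & (kin.timestamps < e.offset)
            assert smoothed[inside].max() >= cfg.speed_threshold
            peak_t = kin.timestamps[inside][np.argmax(smoothed[inside])]
            assert e.onset <= peak_t < e.offset


class TestChenWalton:
    def test_plateau_onset_offset(self):
        # 20 deg/s for 500 ms flanked by rest: onset = first plateau sample,
        # offset = first sample after it
        n_pad, n_plateau = 45, 45
        speed = np.concatenate(
            [np.zeros(n_pad), np.full(n_plateau, 20.0), np.zeros(n_pad)]
        )
        events = chen_walton_classify(speed, CwConfig(), RATE)
        assert len(events) == 1
        dt = 1 / RATE
        assert events[0].onset == pytest.approx(n_pad * dt)
        assert events[0].offset == pytest.approx((n_pad + n_plateau) * dt)

    def test_subthreshold_series_empty(self):
        assert chen_walton_classify(np.full(500, 5.0), CwConfig(), RATE) == []
        assert chen_walton_classify(np.full(3, 50.0), CwConfig(), RATE) == []

    def test_long_gap_splits_event(self):
        speed = np.concatenate(
            [np.zeros(45), np.full(30, 20.0), np.zeros(4), np.full(30, 20.0), np.zeros(45)]
        )
        events = chen_walton_classify(speed, CwConfig(), RATE)
        assert len(events) == 2

    def test_one_sample_gap_does_not_split(self):
        # the 22 ms / 2-sample offset window needs 2 consecutive below-
        # threshold samples; a single-sample dip cannot close the event
        speed = np.concatenate(
            [np.zeros(45), np.full(30, 20.0), np.zeros(1), np.full(30, 20.0), np.zeros(45)]
        )
        events = chen_walton_classify(speed, CwConfig(), RATE)
        assert len(events) == 1

    def test_streaming_scan_matches_bruteforce_oracle(self, cw_oracle):
        rng = np.random.default_rng(5)
        cfg = CwConfig()
        dt = 1 / RATE
        for _ in range(25):
            n = int(rng.integers(9, 2000))
            speed = np.abs(
                np.convolve(rng.normal(0, 10, n), np.ones(5) / 5, mode="same")
            )
            got = chen_walton_classify(speed, cfg, RATE)
            want = cw_oracle(speed, cfg, RATE)
            got_idx = [
                (round(e.onset / dt), round(e.offset / dt)) for e in got
            ]
            assert got_idx == want

    def test_every_event_contains_above_threshold_sample(self):
        rng = np.random.default_rng(6)
        speed = np.abs(rng.normal(0, 8, 3000))
        cfg = CwConfig()
        t = np.arange(len(speed)) / RATE
        for e in chen_walton_classify(speed, cfg, RATE, t):
            inside = (t >= e.onset) & (t < e.offset)
            assert (speed[inside] > cfg.speed_threshold).any()


def _ramp_trace(h_rate_end=40.0, v_rate_end=0.0, n=270):
    """Trace with linearly increasing yaw/pitch rates (constant acceleration)."""
    t = np.arange(n) / RATE
    yaw = 0.5 * h_rate_end / t[-1] * t**2       # rate grows 0 -> h_rate_end
    pitch = -0.5 * v_rate_end / t[-1] * t**2    # negative pitch = upward
    from scipy.spatial.transform import Rotation

    ang = np.column_stack([yaw, pitch, np.zeros(n)])
    quat = Rotation.from_euler("YXZ", ang, degrees=True).as_quat()
    return OrientationTrace(timestamps=t, quat=quat, sample_rate=RATE)


class TestDizco:
    def test_single_axis_ramp_gives_one_cardinal_event(self):
        kin = compute_kinematics(_ramp_trace(h_rate_end=40.0))
        events = dizco_classify(kin, DizcoConfig(accel_magnitude_threshold=5.0))
        assert len(events) == 1
        assert events[0].direction == "E"

    def test_equal_ramps_give_diagonal_label(self):
        kin = compute_kinematics(_ramp_trace(h_rate_end=40.0, v_rate_end=40.0))
        events = dizco_classify(kin, DizcoConfig(accel_magnitude_threshold=5.0))
        assert len(events) == 1
        assert events[0].direction == "NE"

    def test_subthreshold_noise_is_rest(self):
        rng = np.random.default_rng(7)
        t = np.arange(300) / RATE
        from scipy.spatial.transform import Rotation

        ang = rng.normal(0, 1e-4, (300, 3))
        quat = Rotation.from_euler("YXZ", ang, degrees=True).as_quat()
        kin = compute_kinematics(OrientationTrace(timestamps=t, quat=quat))
        events = dizco_classify(kin, DizcoConfig(accel_magnitude_threshold=50.0))
        assert events == []

    def test_mirror_equivariance_flips_left_right_only(self):
        for v_end, direction, mirrored in [
            (0.0, "E", "W"),
            (40.0, "NE", "NW"),
        ]:
            kin = compute_kinematics(_ramp_trace(40.0, v_end))
            kin_m = compute_kinematics(_ramp_trace(-40.0, v_end))
            cfg = DizcoConfig(accel_magnitude_threshold=5.0)
            assert dizco_classify(kin, cfg)[0].direction == direction
            assert dizco_classify(kin_m, cfg)[0].direction == mirrored


class TestTree:
    def _separable(self, rng, n=4000):
        speed = rng.uniform(0, 20, n)
        head_angle = rng.uniform(0, 60, n)
        features = np.column_stack([speed, head_angle])
        y = labels(speed > 10.0)
        return features, y

    def test_separable_data_learned_nearly_perfectly(self):
        rng = np.random.default_rng(8)
        features, y = self._separable(rng)
        half = len(features) // 2
        model = tree_train(features[:half], labels(y.moving[:half]))
        pred = tree_classify(model, features[half:], y.timestamps[half:])
        assert np.mean(pred.moving == y.moving[half:]) >= 0.99
        assert model.get_depth() <= 10

    def test_random_labels_score_at_majority_rate(self):
        rng = np.random.default_rng(9)
        n = 3000
        features = np.column_stack([rng.uniform(0, 20, n), rng.uniform(0, 60, n)])
        y = labels(rng.random(n) < 0.3)  # independent of features
        acc = tree_cv_accuracy(features, y, TreeConfig())
        majority = max(np.mean(y.moving), 1 - np.mean(y.moving))
        assert abs(acc - majority) < 0.1

    def test_resubstitution_bounds_cv_accuracy(self):
        rng = np.random.default_rng(10)
        features, y = self._separable(rng, n=2000)
        noisy = y.moving ^ (rng.random(2000) < 0.2)
        model = tree_train(features, labels(noisy))
        resub = np.mean(model.predict(features) == noisy)
        cv = tree_cv_accuracy(features, labels(noisy))
        assert resub >= cv - 1e-9

    def test_constant_features_give_constant_label(self):
        rng = np.random.default_rng(11)
        features, y = self._separable(rng, n=500)
        model = tree_train(features, y)
        zeros = np.zeros((50, 2))
        pred = tree_classify(model, zeros, np.arange(50) / RATE)
        assert len(set(pred.moving.tolist())) == 1

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            tree_train(np.zeros((20, 2)), labels(np.ones(20)))

    def test_predictions_match_manual_tree_traversal(self):
        # independent re-derivation of per-sample labels by walking the
        # fitted tree's node arrays explicitly
        rng = np.random.default_rng(12)
        features, y = self._separable(rng, n=2000)
        noisy = y.moving ^ (rng.random(2000) < 0.1)
        model = tree_train(features, labels(noisy))
        test = np.column_stack([rng.uniform(0, 20, 1000), rng.uniform(0, 60, 1000)])
        tree = model.tree_

        def walk(x):
            node = 0
            while tree.children_left[node] != -1:
                if x[tree.feature[node]] <= tree.threshold[node]:
                    node = tree.children_left[node]
                else:
                    node = tree.children_right[node]
            return bool(np.argmax(tree.value[node]))

        manual = np.array([walk(x) for x in test])
        pred = tree_classify(model, test, np.arange(1000) / RATE).moving
        assert np.mean(manual == pred) >= 0.99


class TestEventLabelConversion:
    def test_run_length_example(self):
        ls = labels([0, 1, 1, 0, 1, 0])
        events = labels_to_events(ls)
        assert len(events) == 2
        dt = 1 / RATE
        assert events[0].onset == pytest.approx(1 * dt)
        assert events[0].offset == pytest.approx(3 * dt)

    def test_all_zeros(self):
        assert labels_to_events(labels(np.zeros(20))) == []

    def test_round_trip_identity_on_random_series(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            bits = rng.random(rng.integers(2, 60)) < 0.4
            ls = labels(bits)
            back = events_to_labels(labels_to_events(ls), ls.timestamps)
            assert (back.moving == ls.moving).all()


class TestPruneShortIntervals:
    def test_rule_application(self):
        events = [
            MovementEvent(0.0, 0.1),
            MovementEvent(0.2, 0.5),
            MovementEvent(0.6, 1.0),
        ]
        kept = prune_short_intervals(events, reference_mean_duration=0.4)
        assert len(kept) == 2 and kept[0].duration == pytest.approx(0.3)

    def test_empty_input(self):
        assert prune_short_intervals([], 0.4) == []

    def test_exact_cutoff_kept(self):
        events = [MovementEvent(0.0, 0.2), MovementEvent(0.3, 0.5)]
        assert len(prune_short_intervals(events, 0.4)) == 2


class TestAnnotateEvents:
    def test_monotone_yaw_amplitude(self):
        yaw = np.concatenate([np.zeros(30), np.linspace(0, 30, 60), np.full(30, 30.0)])
        trace = yaw_trace(yaw)
        kin = compute_kinematics(trace)
        dt = 1 / RATE
        events = annotate_events([MovementEvent(30 * dt, 90 * dt)], trace, kin)
        assert events[0].amplitude == pytest.approx(30.0, abs=0.6)

    def test_return_to_start_has_zero_amplitude(self):
        yaw = np.concatenate([np.linspace(0, 20, 45), np.linspace(20, 0, 45)])
        trace = yaw_trace(yaw)
        kin = compute_kinematics(trace)
        events = annotate_events([MovementEvent(0.0, 89 / RATE)], trace, kin)
        assert events[0].amplitude == pytest.approx(0.0, abs=0.5)
        assert events[0].peak_velocity > 0

    def test_raised_cosine_peak_velocity(self):
        # 20 deg movement over 0.5 s: peak velocity 2A/T = 80 deg/s
        n = 46
        tau = np.arange(n) / (n - 1)
        yaw = 20.0 * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
        yaw = np.concatenate([np.zeros(20), yaw, np.full(20, 20.0)])
        trace = yaw_trace(yaw)
        kin = compute_kinematics(trace)
        dt = 1 / RATE
        events = annotate_events([MovementEvent(20 * dt, 66 * dt)], trace, kin)
        assert events[0].peak_velocity == pytest.approx(80.0, rel=0.02)

    def test_event_outside_trace_rejected(self):
        trace = yaw_trace(np.zeros(30))
        kin = compute_kinematics(trace)
        with pytest.raises(ValueError, match="outside"):
            annotate_events([MovementEvent(1.0, 2.0)], trace, kin)


def test_all_classifier_events_sorted_disjoint_within_span():
    from headmov.synthdata import SimConfig, simulate_trace

    cfg = SimConfig(seed=21, n_trials=4, noise_sd_deg=0.02)
    sim = simulate_trace(cfg)
    kin = compute_kinematics(sim.trace)
    runs = {
        "svt": svt_classify(kin, SvtConfig(speed_threshold=10)),
        "cw": chen_walton_classify(kin.speed, CwConfig(), kin.rate, kin.timestamps),
        "dizco": dizco_classify(kin, DizcoConfig(), markers=sim.markers),
    }
    t0, t1 = kin.timestamps[0], kin.timestamps[-1] + kin.dt
    for name, events in runs.items():
        assert events, name
        for e in events:
            assert t0 <= e.onset < e.offset <= t1 + 1e-9, name
        for a, b in zip(events, events[1:]):
            assert b.onset >= a.offset, name
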