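"""Touchpoint detection and the twelve per-trial metrics."""

import dataclasses

import numpy as np
import pytest

import palpmetrics as pm
from palpmetrics.errors import EmptyWindow, TooFewFrames
from palpmetrics.metrics import METRIC_NAMES

from conftest import full_bundle


def gridded(b, rate=100.0):
    return pm.resample_to_grid(b, rate)


def window(a, b):
    return pm.PalpationWindow(a, b, "manual", "ok")


def brute_force_metrics(rb, w, tps, motor, rcm_thr=20.0, rntp_radius=40.0):
    """Independent single-pass recomputation of the per-trial metrics."""
    t = rb.channels["force_index"].t
    m = (t >= w.T_start - 1e-9) & (t <= w.T_end + 1e-9)
    comb = rb.channels["force_index"].v[m] + rb.channels["force_middle"].v[m]
    x = rb.channels["finger_x"].v[m]
    y = rb.channels["finger_y"].v[m]
    W = w.T_end - w.T_start

    dwell = 0.0
    total = 0.0
    for tp in tps:
        dwell += tp.TPT
        total += tp.TPT * tp.TPF
    path = 0.0
    for i in range(1, len(x)):
        if np.isfinite(x[i - 1]) and np.isfinite(x[i]) and np.isfinite(y[i - 1]) and np.isfinite(y[i]):
            path += float(np.hypot(x[i] - x[i - 1], y[i] - y[i - 1]))
    fin = [v for v in comb if np.isfinite(v)]
    proj = pm.compute_velocity_projection(t[m], x, y, motor)
    toward = sum(1 for v in proj.V_p if np.isfinite(v) and v > rcm_thr)
    sig = sum(1 for v in proj.V_p if np.isfinite(v) and abs(v) > rcm_thr)
    located = [tp for tp in tps if tp.located]
    near = sum(1 for tp in located if tp.TPD < rntp_radius)
    return {
        "touchpoints": len(tps),
        "frequency": len(tps) / W,
        "total_force": total,
        "force_range": max(fin) - min(fin) if fin else np.nan,
        "dwell_time": dwell,
        "idle_time": W - dwell,
        "path_length": path,
        "rcm": 100.0 * toward / sig if sig else None,
        "rntp": 100.0 * near / len(located) if located else None,
        "mean_tpt": float(np.mean([tp.TPT for tp in tps])) if tps else np.nan,
        "mean_tpf": float(np.mean([tp.TPF for tp in tps])) if tps else np.nan,
        "mean_tpd": float(np.mean([tp.TPD for tp in located])) if located else None,
    }


class TestDetectTouchpoints:
    def test_triangular_pulse_geometry(self, layout):
        # triangle apex 1.0 N at t=5, base width 2 s: half-prominence width = 1 s
        rate = 100.0
        t = np.arange(0.0, 20.0, 1.0 / rate)
        tri = np.clip(1.0 - np.abs(t - 5.0), 0.0, None)
        rb = gridded(full_bundle(force_index=(t, tri)))
        tps = pm.detect_touchpoints(rb, window(3.0, 8.0), layout)
        assert len(tps) == 1
        assert tps[0].t_tp == pytest.approx(5.0, abs=1.0 / rate)
        assert tps[0].TPF == pytest.approx(1.0, abs=1e-9)
        assert tps[0].TPT == pytest.approx(1.0, abs=2.0 / rate)

    def test_five_gaussians_counted_exactly(self, layout):
        rate = 100.0
        t = np.arange(0.0, 20.0, 1.0 / rate)
        centers = [4.0, 6.0, 8.5, 11.0, 14.0]
        f = sum(0.4 * np.exp(-0.5 * ((t - c) / 0.15) ** 2) for c in centers)
        rb = gridded(full_bundle(force_index=(t, f)))
        tps = pm.detect_touchpoints(rb, window(2.0, 16.0), layout)
        assert len(tps) == 5
        for tp, c in zip(tps, centers):
            assert tp.t_tp == pytest.approx(c, abs=1.0 / rate)

    def test_zero_duration_window_raises(self, layout):
        rb = gridded(full_bundle())
        with pytest.raises(EmptyWindow):
            pm.detect_touchpoints(rb, window(5.0, 5.0), layout)

    def test_missing_position_keeps_force_info(self, layout):
        rate = 100.0
        t = np.arange(0.0, 10.0, 1.0 / rate)
        f = 0.5 * np.exp(-0.5 * ((t - 5.0) / 0.2) ** 2)
        # fingertip channel with a hole spanning the peak
        t_pos = np.concatenate([t[t < 4.0], t[t > 6.0]])
        rb = gridded(
            full_bundle(
                force_index=(t, f),
                finger_x=(t_pos, np.zeros_like(t_pos)),
                finger_y=(t_pos, np.zeros_like(t_pos)),
            )
        )
        tps = pm.detect_touchpoints(rb, window(2.0, 9.0), layout)
        assert len(tps) == 1
        assert not tps[0].located
        assert tps[0].TPF == pytest.approx(0.5, abs=0.01)


class TestVelocityProjection:
    def test_straight_toward_motor(self):
        t = np.arange(0.0, 2.0, 0.01)
        x = 100.0 - 50.0 * t  # motor at origin, approach along x at 50 mm/s
        y = np.zeros_like(t)
        proj = pm.compute_velocity_projection(t, x, y, (0.0, 0.0))
        core = proj.V_p[5:-5]
        np.testing.assert_allclose(core, 50.0, atol=1e-6)

    def test_straight_away_is_negative(self):
        t = np.arange(0.0, 2.0, 0.01)
        x = 100.0 + 50.0 * t
        proj = pm.compute_velocity_projection(t, x, np.zeros_like(t), (0.0, 0.0))
        np.testing.assert_allclose(proj.V_p[5:-5], -50.0, atol=1e-6)

    def test_circular_motion_projects_to_zero(self):
        # constant-radius orbit around the motor: radial velocity ~ 0
        t = np.arange(0.0, 5.0, 0.01)
        speed = 50.0
        r = 60.0
        ang = speed / r * t
        proj = pm.compute_velocity_projection(
            t, r * np.cos(ang), r * np.sin(ang), (0.0, 0.0)
        )
        assert np.nanmax(np.abs(proj.V_p[5:-5])) < 0.02 * speed

    def test_too_few_frames_raises(self):
        with pytest.raises(TooFewFrames):
            pm.compute_velocity_projection([0.0, 0.1], [0.0, 1.0], [0.0, 0.0], (0, 0))


class TestRatios:
    def test_rcm_all_toward(self):
        proj = pm.ProjectionSeries(np.arange(10.0), np.full(10, 50.0))
        assert pm.compute_rcm(proj) == 100.0

    def test_rcm_symmetric_is_half(self):
        v = np.array([50.0, -50.0] * 10)
        assert pm.compute_rcm(pm.ProjectionSeries(np.arange(20.0), v)) == 50.0

    def test_rcm_undefined_below_threshold(self):
        v = np.full(30, 10.0)
        assert pm.compute_rcm(pm.ProjectionSeries(np.arange(30.0), v)) is None

    def test_rcm_matches_recount_on_random_walk(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 40, 500)
        v[rng.random(500) < 0.1] = np.nan
        proj = pm.ProjectionSeries(np.arange(500.0), v)
        got = pm.compute_rcm(proj)
        toward = sum(1 for u in v if np.isfinite(u) and u > 20.0)
        sig = sum(1 for u in v if np.isfinite(u) and abs(u) > 20.0)
        assert got == pytest.approx(100.0 * toward / sig, abs=1e-12)

    def test_rntp_all_at_motor(self):
        tps = [pm.Touchpoint(1.0, 0.3, 0.5, 0.0, 0.0, 0.0) for _ in range(4)]
        assert pm.compute_rntp(tps) == 100.0

    def test_rntp_strict_boundary(self):
        # 40.0 mm is excluded by the strict inequality
        tps = [
            pm.Touchpoint(float(i), 0.3, 0.5, 0.0, 0.0, d)
            for i, d in enumerate([10.0, 39.9, 40.0, 100.0])
        ]
        assert pm.compute_rntp(tps) == 50.0

    def test_rntp_undefined_without_locations(self):
        assert pm.compute_rntp([]) is None
        assert pm.compute_rntp([pm.Touchpoint(1.0, 0.3, 0.5)]) is None


class TestTrialMetrics:
    def _metrics_for(self, layout, tps, T=10.0):
        rb = gridded(full_bundle(duration=T + 2))
        return pm.compute_trial_metrics(rb, window(0.0, T), tps, layout)

    def test_frequency_and_time_partition(self, layout):
        tps = [pm.Touchpoint(float(i), 0.2, 0.5) for i in range(10)]
        m = self._metrics_for(layout, tps, T=10.0)
        assert m.frequency == pytest.approx(1.0)
        assert m.dwell_time + m.idle_time == pytest.approx(10.0, abs=1e-9)

    def test_total_force_dwell_idle(self, layout):
        tps = [pm.Touchpoint(1.0, 1.0, 2.0), pm.Touchpoint(5.0, 2.0, 3.0)]
        m = self._metrics_for(layout, tps, T=10.0)
        assert m.total_force == pytest.approx(8.0)
        assert m.dwell_time == pytest.approx(3.0)
        assert m.idle_time == pytest.approx(7.0)

    def test_force_range(self, layout):
        t = np.arange(0.0, 3.0, 0.01)
        f = np.interp(t, [0, 1, 2, 3], [0.1, 0.5, 0.3, 0.3])
        rb = gridded(full_bundle(duration=3.0, force_index=(t, f)))
        m = pm.compute_trial_metrics(rb, window(0.0, 2.9), [], layout)
        assert m.force_range == pytest.approx(0.4, abs=1e-9)

    def test_path_length_square_and_stationary(self, layout):
        t = np.arange(0.0, 4.01, 0.01)
        corners_t = [0, 1, 2, 3, 4]
        xs = np.interp(t, corners_t, [0, 10, 10, 0, 0])
        ys = np.interp(t, corners_t, [0, 0, 10, 10, 0])
        rb = gridded(full_bundle(duration=4.02, finger_x=(t, xs), finger_y=(t, ys)))
        m = pm.compute_trial_metrics(rb, window(0.0, 4.0), [], layout)
        assert m.path_length == pytest.approx(40.0, rel=1e-6)
        rb0 = gridded(full_bundle(duration=4.02))
        m0 = pm.compute_trial_metrics(rb0, window(0.0, 4.0), [], layout)
        assert m0.path_length == pytest.approx(0.0, abs=1e-9)

    def test_append_monotonicity(self, layout):
        tps = [pm.Touchpoint(float(i), 0.3, 0.4 + 0.1 * i) for i in range(6)]
        prev = None
        for k in range(len(tps) + 1):
            m = self._metrics_for(layout, tps[:k], T=10.0)
            if prev is not None:
                assert m.touchpoints >= prev.touchpoints
                assert m.dwell_time >= prev.dwell_time - 1e-12
                assert m.total_force >= prev.total_force - 1e-12
            prev = m

    def test_rigid_rotation_invariance(self, layout, profiles):
        b, gt = pm.generate_trial(profiles["HP"], layout, seed=9)
        rb = pm.resample_to_grid(b, 100.0)
        w = pm.detect_palpation_window(rb)
        tps = pm.detect_touchpoints(rb, w, layout)
        m = pm.compute_trial_metrics(rb, w, tps, layout)

        a = np.deg2rad(73.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        ch = dict(rb.channels)
        xy = np.stack([ch["finger_x"].v, ch["finger_y"].v], axis=1) @ R.T
        ch["finger_x"] = pm.ChannelSeries("finger_x", ch["finger_x"].t, xy[:, 0])
        ch["finger_y"] = pm.ChannelSeries("finger_y", ch["finger_y"].t, xy[:, 1])
        rb2 = dataclasses.replace(rb, channels=ch)
        motor2 = R @ layout.motor(b.fistula_id)
        fist = layout.fistulas[b.fistula_id]
        lay2 = pm.SimulatorLayout(
            fistulas={
                **layout.fistulas,
                b.fistula_id: pm.Fistula(axis=fist.axis, motor=tuple(motor2)),
            },
            bed_radius=layout.bed_radius,
        )
        tps2 = pm.detect_touchpoints(rb2, w, lay2)
        m2 = pm.compute_trial_metrics(rb2, w, tps2, lay2)
        assert m2.path_length == pytest.approx(m.path_length, rel=1e-9)
        assert m2.mean_tpd == pytest.approx(m.mean_tpd, rel=1e-9)
        assert m2.rntp == pytest.approx(m.rntp, abs=1e-9)

    def test_matches_brute_force_on_synthetic_trials(self, profiles, layout):
        for seed, g in [(1, "LP"), (2, "MP"), (3, "HP"), (4, "LP"), (5, "HP")]:
            b, _ = pm.generate_trial(profiles[g], layout, seed=seed)
            rb = pm.resample_to_grid(b, 100.0)
            w = pm.detect_palpation_window(rb)
            assert w.status == "ok"
            tps = pm.detect_touchpoints(rb, w, layout)
            m = pm.compute_trial_metrics(rb, w, tps, layout).as_dict()
            ref = brute_force_metrics(rb, w, tps, layout.motor(b.fistula_id))
            for k in METRIC_NAMES:
                if ref[k] is None:
                    assert m[k] is None
                else:
                    assert m[k] == pytest.approx(ref[k], abs=1e-9), k
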