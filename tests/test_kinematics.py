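import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexawalk.config import LEG_IDS, default_walker_config
from hexawalk.kinematics import (KinematicsError, body_frame,
                                 body_velocities, protraction_angles,
                                 sliding_median)
from hexawalk.walker import Trial, simulate_trial


def static_trial(markers, n=5, frame_rate=50.0):
    times = np.arange(n) / frame_rate
    return Trial(animal_id="x", cohort="x", frame_rate_hz=frame_rate,
                 times_s=times,
                 markers={k: np.tile(np.asarray(v, float), (n, 1))
                          for k, v in markers.items()})


def full_marker_set(heading_deg=0.0, femur_angles=None):
    """Nine-marker layout with body axis at the given arena heading and
    given protraction angles (default: all lateral, i.e. 0 deg)."""
    femur_angles = femur_angles or {}
    h = np.radians(heading_deg)
    rot = np.array([[np.cos(h), -np.sin(h)], [np.sin(h), np.cos(h)]])
    body = {"T1": (25.0, 0.0), "T2": (12.0, 0.0), "T3": (0.0, 0.0)}
    out = {k: rot @ np.asarray(v) for k, v in body.items()}
    seg = {"1": "T1", "2": "T2", "3": "T3"}
    for leg in LEG_IDS:
        a = np.radians(femur_angles.get(leg, 0.0))
        side = 1.0 if leg.startswith("L") else -1.0
        d = np.array([np.sin(a), side * np.cos(a)])
        out[leg] = rot @ (np.asarray(body[seg[leg[1]]]) + 15.0 * d)
    return out


class TestBodyFrame:
    @pytest.mark.parametrize("heading", [0.0, 90.0, -37.0, 135.0])
    def test_heading_matches_axis_direction(self, heading):
        trial = static_trial(full_marker_set(heading))
        bf = body_frame(trial)
        assert np.allclose((bf.heading_deg - heading + 180) % 360 - 180, 0,
                           atol=1e-9)

    def test_simulated_yaw_ramp_recovered(self):
        from dataclasses import replace
        cfg = replace(default_walker_config(period_jitter_sd_s=0.0,
                                            angle_noise_sd_deg=0.0),
                      yaw_deg_s=15.0)
        trial, truth = simulate_trial(cfg, 5.0, seed=0)
        bf = body_frame(trial)
        assert np.allclose(bf.heading_deg, truth.pose_heading_deg, atol=0.1)

    def test_coincident_markers_rejected(self):
        trial = static_trial({"T1": (0.0, 0.0), "T2": (0.0, 0.0),
                              "T3": (0.0, 0.0)})
        with pytest.raises(KinematicsError, match="coincident"):
            body_frame(trial)

    def test_three_marker_fit_agrees_with_chord_for_collinear_markers(self):
        trial = static_trial(full_marker_set(25.0))
        a = body_frame(trial, axis_fit="chord")
        b = body_frame(trial, axis_fit="fit")
        assert np.allclose(a.heading_deg, b.heading_deg, atol=1e-6)


class TestProtractionAngles:
    def test_lateral_femur_is_zero_degrees(self):
        """Femur orthogonal to the body axis -> protraction angle 0."""
        trial = static_trial(full_marker_set())
        ang = protraction_angles(trial, body_frame(trial))
        for leg in LEG_IDS:
            assert np.allclose(ang[leg].protraction_deg, 0.0, atol=1e-9)

    def test_anterior_parallel_femur_is_plus_ninety(self):
        trial = static_trial(full_marker_set(
            femur_angles={leg: 90.0 for leg in LEG_IDS}))
        ang = protraction_angles(trial, body_frame(trial))
        for leg in LEG_IDS:
            assert np.allclose(ang[leg].protraction_deg, 90.0, atol=1e-9)

    def test_forty_five_forward_on_both_sides(self):
        """+45 deg means 45 forward of lateral on each body side; verified
        against brute-force 2-D geometry of the side-dependent
        perpendicular."""
        trial = static_trial(full_marker_set(
            heading_deg=30.0, femur_angles={leg: 45.0 for leg in LEG_IDS}))
        ang = protraction_angles(trial, body_frame(trial))
        for leg in LEG_IDS:
            assert np.allclose(ang[leg].protraction_deg, 45.0, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(rot=st.floats(-180, 180), tx=st.floats(-50, 50),
           ty=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, rot, tx, ty):
        """Rotating/translating the whole arena leaves angles unchanged
        and adds exactly the rotation to the heading."""
        cfg = default_walker_config(period_jitter_sd_s=0.0,
                                    angle_noise_sd_deg=0.0)
        trial, _ = simulate_trial(cfg, 3.0, seed=2)
        a0 = protraction_angles(trial, body_frame(trial))
        h = np.radians(rot)
        rmat = np.array([[np.cos(h), -np.sin(h)], [np.sin(h), np.cos(h)]])
        moved = Trial(animal_id="x", cohort="x",
                      frame_rate_hz=trial.frame_rate_hz,
                      times_s=trial.times_s,
                      markers={k: v @ rmat.T + [tx, ty]
                               for k, v in trial.markers.items()})
        bf0, bf1 = body_frame(trial), body_frame(moved)
        a1 = protraction_angles(moved, bf1)
        dh = (bf1.heading_deg - bf0.heading_deg - rot + 180) % 360 - 180
        assert np.allclose(dh, 0, atol=1e-6)
        for leg in LEG_IDS:
            assert np.allclose(a0[leg].protraction_deg,
                               a1[leg].protraction_deg, atol=1e-6)

    def test_mirror_swaps_sides_and_negates_ty_rot(self):
        """Mirroring across the body axis swaps L/R angle series and
        negates sideward and rotational velocity."""
        from dataclasses import replace
        cfg = replace(default_walker_config(period_jitter_sd_s=0.0,
                                            angle_noise_sd_deg=0.0),
                      vy_mm_s=5.0, yaw_deg_s=8.0)
        trial, _ = simulate_trial(cfg, 4.0, seed=3)
        mirrored = Trial(
            animal_id="x", cohort="x", frame_rate_hz=trial.frame_rate_hz,
            times_s=trial.times_s,
            markers={("R" + k[1] if k[0] == "L" else
                      "L" + k[1] if k[0] == "R" else k):
                     v * np.array([1.0, -1.0])
                     for k, v in trial.markers.items()})
        a0 = protraction_angles(trial, body_frame(trial))
        a1 = protraction_angles(mirrored, body_frame(mirrored))
        for leg in LEG_IDS:
            partner = ("R" if leg[0] == "L" else "L") + leg[1]
            assert np.allclose(a0[leg].protraction_deg,
                               a1[partner].protraction_deg, atol=1e-9)
        v0 = body_velocities(body_frame(trial))
        v1 = body_velocities(body_frame(mirrored))
        assert np.allclose(v0.tx_mm_s, v1.tx_mm_s, atol=1e-9)
        assert np.allclose(v0.ty_mm_s, -v1.ty_mm_s, atol=1e-9)
        assert np.allclose(v0.rot_deg_s, -v1.rot_deg_s, atol=1e-9)


class TestVelocities:
    def test_stationary_trial_zero_velocities(self):
        trial = static_trial(full_marker_set(), n=20)
        vel = body_velocities(body_frame(trial))
        assert np.allclose(vel.tx_mm_s, 0) and np.allclose(vel.ty_mm_s, 0)
        assert np.allclose(vel.rot_deg_s, 0)

    def test_pure_forward_translation(self):
        base = full_marker_set(heading_deg=90.0)
        n, rate, speed = 30, 50.0, 30.0
        times = np.arange(n) / rate
        shift = np.stack([np.zeros(n), speed * times], axis=1)
        trial = Trial(animal_id="x", cohort="x", frame_rate_hz=rate,
                      times_s=times,
                      markers={k: np.asarray(v) + shift
                               for k, v in base.items()})
        vel = body_velocities(body_frame(trial))
        assert np.allclose(vel.tx_mm_s, 30.0, atol=1e-9)
        assert np.allclose(vel.ty_mm_s, 0.0, atol=1e-9)
        assert np.allclose(vel.rot_deg_s, 0.0, atol=1e-9)

    def test_simulated_velocities_recovered_within_one_percent(self):
        from dataclasses import replace
        cfg = replace(default_walker_config(period_jitter_sd_s=0.0,
                                            angle_noise_sd_deg=0.0),
                      vx_mm_s=30.0, vy_mm_s=-4.0, yaw_deg_s=12.0)
        trial, _ = simulate_trial(cfg, 5.0, seed=1)
        vel = body_velocities(body_frame(trial), window_ms=60.0)
        sl = slice(2, -2)  # outside the filter's edge region
        assert np.allclose(vel.tx_mm_s[sl], 30.0, rtol=0.01)
        assert np.allclose(vel.ty_mm_s[sl], -4.0, rtol=0.01)
        assert np.allclose(vel.rot_deg_s[sl], 12.0, rtol=0.01)

    def test_sixty_ms_window_is_three_samples_at_fifty_hz(self):
        trial = static_trial(full_marker_set(), n=10)
        # a single outlier frame survives a 1-sample window but not 3
        trial.markers["T3"] = trial.markers["T3"].copy()
        trial.markers["T1"] = trial.markers["T1"].copy()
        trial.markers["T3"][5] += [0.0, 1.0]
        trial.markers["T1"][5] += [0.0, 1.0]
        vel = body_velocities(body_frame(trial), window_ms=60.0)
        assert np.allclose(vel.ty_mm_s, 0.0, atol=1e-9)  # median kills spike
        vel1 = body_velocities(body_frame(trial), window_ms=1.0)
        assert not np.allclose(vel1.ty_mm_s, 0.0, atol=1e-9)

    def test_invalid_window_rejected(self):
        trial = static_trial(full_marker_set(), n=5)
        with pytest.raises(KinematicsError):
            body_velocities(body_frame(trial), window_ms=0.0)


class TestSlidingMedian:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.array_equal(sliding_median(x, 1), x)

    def test_edge_truncation_example(self):
        np.testing.assert_allclose(sliding_median([0.0, 100.0, 0.0], 3),
                                   [50.0, 0.0, 50.0])

    def test_constant_series_unchanged(self):
        x = np.full(11, 7.5)
        assert np.array_equal(sliding_median(x, 5), x)

    def test_even_window_rejected(self):
        with pytest.raises(KinematicsError):
            sliding_median([1.0, 2.0], 2)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30),
           st.sampled_from([1, 3, 5, 7]))
    def test_matches_naive_definition(self, xs, window):
        x = np.asarray(xs)
        got = sliding_median(x, window)
        h = window // 2
        want = [np.median(x[max(0, i - h):i + h + 1]) for i in range(len(x))]
        np.testing.assert_allclose(got, want)
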