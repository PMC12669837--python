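import math
from dataclasses import replace

import numpy as np
import pytest

from beevector.circstats import circ_mean_resultant, circ_sd
from beevector.geometry import DetourConfig, shortcut_turn, wrap_angle
from beevector.synthetic import (
    DanceGenParams,
    FlightGenParams,
    VideoGenParams,
    camera_for,
    gen_cohort,
    gen_dance,
    gen_flight,
    gen_follower_trace,
    gen_video,
)
from beevector.synthetic import _to_px
from beevector.tracking import boundary_angles


class TestGenFlight:
    def test_noise_free_limit_is_straight_line_at_target(self, cfg45):
        target = shortcut_turn(cfg45)
        p = FlightGenParams(intended_bearing_mean=target,
                            kappa_population=1e12, kappa_noise=1e12,
                            turn_rate=1e6, speed_sd=0.0, seed=0)
        traj = gen_flight(cfg45, p)
        rec = boundary_angles(traj, target_angle=target)
        for a in rec.boundary_angles + (rec.angle_last_visible,):
            assert a == pytest.approx(target, abs=0.2)

    def test_zero_turn_rate_keeps_detour_heading(self, cfg45):
        p = FlightGenParams(intended_bearing_mean=-52.0, turn_rate=0.0,
                            kappa_population=1e12, kappa_noise=1e12,
                            speed_sd=0.0, seed=0)
        traj = gen_flight(cfg45, p)
        rec = boundary_angles(traj)
        for a in rec.boundary_angles:
            if np.isfinite(a):
                assert a == pytest.approx(0.0, abs=0.2)

    def test_relaxation_matches_closed_form_oracle(self, cfg45,
                                                   noise_free_params):
        """Heading follows h_t = intended*(1-(1-a)^t); positions are its
        cumulative integral. An independent frame-by-frame recomputation
        must coincide exactly with the generated path."""
        p = noise_free_params
        traj = gen_flight(cfg45, p)
        target = p.intended_bearing_mean
        dt = 1.0 / cfg45.frame_rate
        a = 1.0 - math.exp(-p.turn_rate * dt)
        h, x, y = 0.0, 0.0, 0.0
        for i in range(1, len(traj)):
            h = h + a * wrap_angle(target - h)
            x += p.speed_mean * dt * math.cos(math.radians(h))
            y += p.speed_mean * dt * math.sin(math.radians(h))
            assert traj.x[i] == pytest.approx(x, abs=1e-9)
            assert traj.y[i] == pytest.approx(y, abs=1e-9)

    def test_boundary_sequence_monotonically_approaches_target(
            self, cfg45, noise_free_params):
        target = noise_free_params.intended_bearing_mean
        traj = gen_flight(cfg45, noise_free_params)
        rec = boundary_angles(traj, target_angle=target)
        errs = [abs(e) for e in rec.signed_errors if np.isfinite(e)]
        assert all(b < a for a, b in zip(errs, errs[1:]))

    def test_deterministic_given_seed(self, cfg45):
        p = FlightGenParams(seed=42)
        t1 = gen_flight(cfg45, p, bee_id=7)
        t2 = gen_flight(cfg45, p, bee_id=7)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)
        t3 = gen_flight(cfg45, p, bee_id=8)
        assert not np.array_equal(t1.x, t3.x)

    def test_population_mean_recovery(self, cfg30):
        """With no disoriented bees the circular mean of final bearings
        over 200 bees must sit within its own 95% CI of the intended
        mean."""
        target = shortcut_turn(cfg30)
        # fast relaxation so the final bearing reflects the intended one
        p = FlightGenParams(intended_bearing_mean=target, turn_rate=20.0,
                            seed=11)
        finals = []
        for bee in range(200):
            traj = gen_flight(cfg30, p, bee_id=bee)
            finals.append(math.degrees(math.atan2(traj.y[-1], traj.x[-1])))
        mu, r = circ_mean_resultant(finals)
        se = circ_sd(r) / math.sqrt(len(finals))
        assert abs(wrap_angle(mu - target)) < 1.96 * se + 3.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FlightGenParams(disoriented_fraction=1.5)
        with pytest.raises(ValueError):
            FlightGenParams(speed_mean=0.0)


class TestGenVideo:
    def test_frame_count_equals_trajectory_length(self, cfg45,
                                                  noise_free_params):
        traj = gen_flight(cfg45, noise_free_params)
        vid = camera_for(cfg45)
        frames = gen_video(traj, vid)
        assert frames.shape[0] == len(traj)
        assert frames.shape[1:] == (int(0.84 * 200), int(1.56 * 200))

    def test_straight_crossing_duration_arithmetic(self):
        # a straight 0.44 m/s path from the exit to the downstream edge:
        # ceil((1.56 - 0.2 - margin)/0.44 * 60) frames
        cfg = DetourConfig(detour_relative_angle=0)
        p = FlightGenParams(intended_bearing_mean=0.0, kappa_population=1e12,
                            kappa_noise=1e12, turn_rate=1e6, speed_sd=0.0,
                            seed=0)
        traj = gen_flight(cfg, p)
        usable = 1.56 - 0.2 - 0.04
        expected = math.ceil(usable / 0.44 * 60)
        assert abs(len(traj) - expected) <= 1

    def test_blob_centroid_matches_trajectory_within_one_pixel(
            self, cfg45, noise_free_params):
        traj = gen_flight(cfg45, noise_free_params)
        vid = camera_for(cfg45)
        frames = gen_video(traj, vid)
        for i in (0, len(frames) // 2, len(frames) - 1):
            dark = np.argwhere(frames[i] < 100)
            cy, cx = dark.mean(axis=0)
            ex, ey = _to_px(vid, traj.x[i], traj.y[i])
            assert math.hypot(cx - ex, cy - ey) < 1.0

    def test_out_of_fov_trajectory_rejected(self, cfg45):
        from beevector.tracking import Trajectory

        bad = Trajectory(bee_id=0, frame_index=[0, 1], x=[0.0, 5.0],
                         y=[0.0, 0.0], frame_rate=60)
        with pytest.raises(ValueError, match="FOV"):
            gen_video(bad, camera_for(cfg45))

    def test_determinism_byte_identical(self, cfg45, noise_free_params):
        traj = gen_flight(cfg45, noise_free_params)
        vid = camera_for(cfg45)
        assert np.array_equal(gen_video(traj, vid), gen_video(traj, vid))


class TestGenDance:
    def test_infinite_concentration_collapses_to_mean(self):
        phases = gen_dance(DanceGenParams(n_phases=5, comb_angle_mean=37,
                                          kappa_phase=1e12, seed=0))
        assert all(ph.comb_angle == pytest.approx(37) for ph in phases)

    def test_single_phase(self):
        assert len(gen_dance(DanceGenParams(n_phases=1, seed=0))) == 1

    def test_wide_scatter_produces_over_60deg_deviants(self):
        """At the default concentration nearly every 20-phase dance
        contains at least one phase deviating >±60 deg from the target."""
        hits = 0
        for seed in range(50):
            phases = gen_dance(DanceGenParams(n_phases=20, comb_angle_mean=0,
                                              seed=seed))
            if any(abs(ph.comb_angle) > 60 for ph in phases):
                hits += 1
        assert hits >= 45

    def test_duration_floor_and_resolution(self):
        phases = gen_dance(DanceGenParams(n_phases=200, duration_mean=0.1,
                                          duration_sd=0.2, seed=1))
        for ph in phases:
            assert ph.duration >= 0.05
            assert (ph.duration / 0.05) == pytest.approx(
                round(ph.duration / 0.05), abs=1e-9)


class TestFollowerTrace:
    def test_zero_noise_round_trip_identity(self):
        phases = gen_dance(DanceGenParams(n_phases=3, comb_angle_mean=37,
                                          kappa_phase=1e12, seed=0))
        trace = gen_follower_trace(phases, noise_sd=0.0, seed=0)
        from beevector.dance import assimilate_phase

        for pid in trace["phase_id"].unique():
            v = assimilate_phase(trace, phase_id=pid)
            assert v.angle == pytest.approx(37, abs=1e-6)

    def test_offset_follower_midpoint_compensates(self):
        """A follower standing 90 deg off the dance axis carries the
        dance direction in her antennal midpoint at -90 deg to her body."""
        phases = gen_dance(DanceGenParams(n_phases=1, comb_angle_mean=0,
                                          kappa_phase=1e12, seed=0))
        trace = gen_follower_trace(phases, heading_offset=90.0, noise_sd=0.0,
                                   seed=0)
        from beevector.dance import antennal_midpoint

        mid = antennal_midpoint(trace["left_ant_deg"].iloc[0],
                                trace["right_ant_deg"].iloc[0])
        assert mid == pytest.approx(-90, abs=1e-9)

    def test_hive_camera_frame_rate(self):
        phases = gen_dance(DanceGenParams(n_phases=1, duration_mean=0.5,
                                          duration_sd=0.0, seed=0))
        trace = gen_follower_trace(phases, seed=0)
        assert trace.attrs["frame_rate"] == 80.0
        assert len(trace) == round(phases[0].duration * 80)


class TestGenCohort:
    def test_rejects_empty_cohort(self, cfg45):
        with pytest.raises(ValueError):
            gen_cohort(cfg45, FlightGenParams(), 0)

    def test_flagged_fraction_near_binomial_expectation(self, cfg45):
        meta, _ = gen_cohort(cfg45, FlightGenParams(), 50, seed=3,
                             exclusion_fraction=0.2)
        flagged = ((meta.stopped) | (meta.exit_duration_s > 30)).sum()
        assert 4 <= flagged <= 17  # Binomial(50, .2) central range

    def test_both_roles_present(self, cfg45):
        meta, _ = gen_cohort(cfg45, FlightGenParams(), 60, seed=4)
        assert set(meta.role) == {"forager", "recruit"}
        assert set(meta.loc[meta.role == "recruit",
                            "detour_angle_deg"]) <= {-30.0, 0.0, 30.0}

    def test_deterministic(self, cfg45):
        m1, t1 = gen_cohort(cfg45, FlightGenParams(), 10, seed=5)
        m2, t2 = gen_cohort(cfg45, FlightGenParams(), 10, seed=5)
        assert m1.equals(m2)
        assert all(np.array_equal(t1[k].x, t2[k].x) for k in t1)
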