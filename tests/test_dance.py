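import math

import numpy as np
import pandas as pd
import pytest

from beevector.circstats import circ_mean_resultant, circ_sd
from beevector.dance import (
    AssimilatedVector,
    antennal_midpoint,
    assimilate_phase,
    dancer_summary,
    detect_follower,
    duration_to_distance,
    follower_mean_vector,
    waggle_angle_from_thorax,
)
from beevector.geometry import wrap_angle
from beevector.synthetic import DanceGenParams, gen_dance, gen_follower_trace


class TestWaggleAngle:
    @pytest.mark.parametrize("start,end,expected", [
        ((0, 0), (0, 1), 0.0),     # straight up the comb
        ((0, 0), (1, 0), 90.0),    # clockwise-positive quarter turn
        ((0, 0), (0, -1), 180.0),
        ((1, 1), (0, 1), -90.0),
    ])
    def test_examples(self, start, end, expected):
        assert waggle_angle_from_thorax(start, end) == pytest.approx(expected)

    def test_generator_round_trip(self):
        ang = 37.0
        th = math.radians(ang)
        end = (math.sin(th), math.cos(th))  # comb convention
        assert waggle_angle_from_thorax((0, 0), end) == pytest.approx(37.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            waggle_angle_from_thorax((1, 2), (1, 2))


class TestDetectFollower:
    BL = 0.013

    def test_close_and_facing(self):
        assert detect_follower((0, 0), 0.0, (0, self.BL / 2))

    def test_too_far(self):
        assert not detect_follower((0, 0), 0.0, (0, 2 * self.BL))

    def test_facing_away(self):
        assert not detect_follower((0, 0), 180.0, (0, self.BL / 2))

    def test_rotation_symmetry(self):
        for rot in (0, 45, 133, -90):
            th = math.radians(rot)
            pos = (self.BL / 2 * math.sin(th), self.BL / 2 * math.cos(th))
            assert detect_follower((0, 0), rot, pos)


class TestAntennalMidpoint:
    @pytest.mark.parametrize("left,right,expected", [
        (30, -30, 0.0),
        (170, -170, 180.0),   # circular, not linear, midpoint
        (45, 45, 45.0),
    ])
    def test_examples(self, left, right, expected):
        assert antennal_midpoint(left, right) == pytest.approx(expected)

    def test_unit_vector_sum_oracle(self):
        left, right = 110.0, -40.0
        s = math.sin(math.radians(left)) + math.sin(math.radians(right))
        c = math.cos(math.radians(left)) + math.cos(math.radians(right))
        expected = math.degrees(math.atan2(s, c))
        assert antennal_midpoint(left, right) == pytest.approx(expected)

    def test_antipodal_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(antennal_midpoint(90.0, -90.0))


def constant_trace(n, gravity, left, right, phase_id=0):
    return pd.DataFrame({
        "phase_id": phase_id, "frame": range(n),
        "gravity_heading_deg": gravity,
        "left_ant_deg": left, "right_ant_deg": right,
    })


class TestAssimilatePhase:
    def test_noise_free_round_trip(self):
        phases = gen_dance(DanceGenParams(n_phases=2, comb_angle_mean=37,
                                          kappa_phase=1e12, seed=0))
        trace = gen_follower_trace(phases, noise_sd=0.0, seed=0)
        v = assimilate_phase(trace, phase_id=0)
        assert v.angle == pytest.approx(37.0, abs=1e-6)
        v_rel = assimilate_phase(trace, phase_id=0, feeder_comb_angle=37.0)
        assert v_rel.angle == pytest.approx(0.0, abs=1e-6)

    def test_uniform_midpoints_give_negligible_magnitude(self):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame({
            "phase_id": 0, "frame": range(n),
            "gravity_heading_deg": 0.0,
            "left_ant_deg": rng.uniform(-180, 180, n),
            "right_ant_deg": rng.uniform(-180, 180, n),
        })
        v = assimilate_phase(df)
        assert v.magnitude < 0.2 * n

    def test_accumulation_linearity(self):
        full = constant_trace(40, 10.0, 20.0, 20.0)
        half = constant_trace(20, 10.0, 20.0, 20.0)
        v_full = assimilate_phase(full)
        v_half = assimilate_phase(half)
        assert v_full.angle == pytest.approx(v_half.angle)
        assert v_full.magnitude == pytest.approx(2 * v_half.magnitude)

    def test_rotation_equivariance_in_gravity(self):
        base = assimilate_phase(constant_trace(10, 15.0, 30.0, -10.0))
        rot = assimilate_phase(constant_trace(10, 15.0 + 40.0, 30.0, -10.0))
        assert wrap_angle(rot.angle - base.angle) == pytest.approx(40.0)

    def test_all_flagged_frames_error(self):
        df = constant_trace(5, 0.0, 90.0, -90.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="flagged"):
                assimilate_phase(df)


class TestFollowerMeanVector:
    def test_identical_phases(self):
        vs = [AssimilatedVector(i, 25.0, 1.0) for i in range(3)]
        assert follower_mean_vector(vs) == pytest.approx(25.0)

    def test_symmetric_cancellation(self):
        vs = [AssimilatedVector(0, 20.0, 1.0), AssimilatedVector(1, -20.0, 1.0)]
        assert follower_mean_vector(vs) == pytest.approx(0.0)

    def test_magnitude_weighting_oracle(self):
        vs = [AssimilatedVector(0, 0.0, 1.0), AssimilatedVector(1, 40.0, 3.0)]
        s = 3 * math.sin(math.radians(40))
        c = 1 + 3 * math.cos(math.radians(40))
        expected = math.degrees(math.atan2(s, c))
        got = follower_mean_vector(vs)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(30.3, abs=0.1)

    def test_phase_order_invariance(self):
        rng = np.random.default_rng(9)
        vs = [AssimilatedVector(i, a, m) for i, (a, m) in enumerate(
            zip(rng.uniform(-90, 90, 8), rng.uniform(0.5, 3, 8)))]
        base = follower_mean_vector(vs)
        for _ in range(5):
            perm = list(rng.permutation(len(vs)))
            assert follower_mean_vector([vs[i] for i in perm]) \
                == pytest.approx(base)

    def test_noisy_round_trip_recovers_dance_mean(self):
        """Noisy traces from several followers: decoded means scatter
        around the generated comb-angle mean."""
        decoded = []
        for fid in range(6):
            phases = gen_dance(DanceGenParams(n_phases=8, comb_angle_mean=30,
                                              kappa_phase=4.0, seed=100 + fid))
            trace = gen_follower_trace(phases, follower_id=fid, noise_sd=10.0,
                                       seed=fid)
            vs = [assimilate_phase(trace, phase_id=p.phase_id)
                  for p in phases]
            decoded.append(follower_mean_vector(vs))
        mu, r = circ_mean_resultant(decoded)
        se = circ_sd(r) / math.sqrt(len(decoded))
        assert abs(wrap_angle(mu - 30)) < 1.96 * se + 5.0


class TestDurationToDistance:
    def test_affine_map(self):
        assert duration_to_distance(0.4, slope=500, intercept=0) == 200.0
        assert duration_to_distance(0.05, slope=100, intercept=2) == 7.0

    def test_round_trip_with_inverse(self):
        d = duration_to_distance(0.35, slope=800, intercept=-10)
        assert (d + 10) / 800 == pytest.approx(0.35)

    def test_floor_and_clamp(self):
        with pytest.raises(ValueError):
            duration_to_distance(0.01)
        with pytest.warns(UserWarning):
            assert duration_to_distance(0.1, slope=1, intercept=-10) == 0.0


class TestDancerSummary:
    def test_perfect_dancer(self):
        dances = pd.DataFrame({"dancer_id": [1, 1, 1],
                               "comb_angle_deg": [10.0, 10.0, 10.0]})
        bearings = pd.DataFrame({"dancer_id": [1],
                                 "error_last_visible": [0.0]})
        out = dancer_summary(dances, bearings, feeder_comb_angle=10.0)
        row = out.iloc[0]
        assert row.dance_mean_error_deg == pytest.approx(0.0)
        assert row.dance_circ_sd_deg == pytest.approx(0.0, abs=1e-6)

    def test_two_dancers_two_rows_and_unmatched_reported(self):
        dances = pd.DataFrame({"dancer_id": [1, 1, 2, 2, 3],
                               "comb_angle_deg": [5.0, -5, 20, 30, 0]})
        bearings = pd.DataFrame({"dancer_id": [1, 2, 4],
                                 "error_last_visible": [3.0, -8.0, 1.0]})
        out = dancer_summary(dances, bearings)
        assert len(out) == 2
        assert out.attrs["unmatched"] == [3, 4]

    def test_independent_noise_shows_no_association(self):
        """Dance s.d. and flight error generated independently:
        their correlation across dancers is near zero."""
        rng = np.random.default_rng(3)
        rows_d, rows_b = [], []
        for did in range(24):
            kappa = rng.uniform(1.0, 6.0)
            angs = np.degrees(rng.vonmises(0.0, kappa, size=15))
            for a in angs:
                rows_d.append({"dancer_id": did, "comb_angle_deg": a})
            for _ in range(3):
                rows_b.append({"dancer_id": did,
                               "error_last_visible":
                               float(np.degrees(rng.vonmises(0.0, 3.0)))})
        out = dancer_summary(pd.DataFrame(rows_d), pd.DataFrame(rows_b))
        r = np.corrcoef(out.dance_circ_sd_deg,
                        np.abs(out.flight_mean_error_deg))[0, 1]
        assert abs(r) < 0.45
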