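"""Dance-side measurement and a baseline vector-assimilation estimator.

A returning forager encodes her food vector in waggle phases: the
angle of the straight waggle run relative to gravity-up on the vertical
comb signals the direction (relative to the solar azimuth), its
duration signals the distance.  A follower within one body length and
facing the dancer experiences the dance mechanically; from her own
heading relative to gravity and the positions of her two antennae one
can estimate, frame by frame, where the dance axis lies and accumulate
a per-phase vector estimate — the quantity a recruit could plausibly
assimilate without any overhead view of the dancer.

The per-phase estimator here is a deliberately simple baseline: the
frame-wise pointing estimate is the follower's gravity heading plus the
circular midpoint of her antennal angles, and the phase vector is the
resultant of unit vectors at those estimates.  It honours the same
input/output contract as neural-circuit models of dance assimilation,
and the operation signature accepts a drop-in replacement.

Comb coordinates: gravity-up = 0 deg, clockwise positive.  Antennal
angles are base-to-tip directions relative to the follower's body axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import circ_mean_resultant, circ_sd
from .geometry import wrap_angle

__all__ = [
    "AssimilatedVector",
    "waggle_angle_from_thorax",
    "detect_follower",
    "antennal_midpoint",
    "assimilate_phase",
    "follower_mean_vector",
    "duration_to_distance",
    "dancer_summary",
]

BODY_LENGTH_M = 0.013  # one bee length


@dataclass
class AssimilatedVector:
    """Per-phase vector estimate from a follower's sensory trace."""

    phase_id: int
    angle: float       # deg; relative to the feeder comb angle if given
    magnitude: float   # resultant length over frames (accumulation units)

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def waggle_angle_from_thorax(start, end) -> float:
    """Comb angle of a waggle run from its thorax start/end points.

    Points are (x, y) comb-plane coordinates with y pointing up against
    gravity; the result is degrees clockwise from gravity-up, wrapped
    to (-180, 180].
    """
    dx, dy = end[0] - start[0], end[1] - start[1]
    if math.hypot(dx, dy) < 1e-12:
        raise ValueError("thorax start and end coincide")
    return float(wrap_angle(math.degrees(math.atan2(dx, dy))))


def detect_follower(candidate_pos, candidate_heading, dancer_pos,
                    body_length: float = BODY_LENGTH_M,
                    cone_half_angle: float = 90.0) -> bool:
    """Is the candidate following the dancer?

    True iff the candidate is within one body length of the dancer and
    the dancer lies within a facing cone about the candidate's heading.
    Positions are comb-plane (x, y) with y up; headings are comb angles
    (clockwise from up).
    """
    dx = dancer_pos[0] - candidate_pos[0]
    dy = dancer_pos[1] - candidate_pos[1]
    dist = math.hypot(dx, dy)
    if dist > body_length:
        return False
    if dist < 1e-12:
        return True
    to_dancer = math.degrees(math.atan2(dx, dy))  # comb convention
    return abs(wrap_angle(to_dancer - candidate_heading)) <= cone_half_angle


def antennal_midpoint(left: float, right: float) -> float:
    """Circular midpoint of the two antennal angles (degrees).

    The angle of the sum of the two unit vectors, so {170, -170} gives
    180, not the linear average 0.  Antipodal antennae leave the
    midpoint undefined: NaN is returned and the frame should be
    skipped.
    """
    lr, rr = math.radians(left), math.radians(right)
    s = math.sin(lr) + math.sin(rr)
    c = math.cos(lr) + math.cos(rr)
    if math.hypot(s, c) < 1e-9:
        warnings.warn("antipodal antennal angles: midpoint undefined")
        return float("nan")
    return float(wrap_angle(math.degrees(math.atan2(s, c))))


def assimilate_phase(trace: pd.DataFrame, phase_id=None,
                     feeder_comb_angle: float = 0.0,
                     linear_midpoint: bool = False) -> AssimilatedVector:
    """Baseline per-phase vector estimate from a follower trace.

    ``trace`` holds per-frame columns ``gravity_heading_deg``,
    ``left_ant_deg``, ``right_ant_deg`` (optionally filtered to one
    ``phase_id``).  Each frame contributes a unit vector at
    gravity heading + antennal midpoint; the phase vector is their
    resultant.  The angle is reported relative to
    ``feeder_comb_angle`` (0 keeps it relative to gravity-up).
    """
    df = trace
    if phase_id is not None:
        df = df[df["phase_id"] == phase_id]
    if len(df) < 2:
        raise ValueError("need at least 2 frames in the phase")
    if linear_midpoint:
        mid = (df["left_ant_deg"].to_numpy() + df["right_ant_deg"].to_numpy()) / 2
    else:
        mid = np.array([antennal_midpoint(l, r) for l, r in
                        zip(df["left_ant_deg"], df["right_ant_deg"])])
    ok = np.isfinite(mid)
    if not ok.any():
        raise ValueError("all frames flagged: no usable antennal midpoints")
    pointing = np.radians(df["gravity_heading_deg"].to_numpy()[ok] + mid[ok])
    # comb convention is clockwise-from-up: cos pairs with the up axis
    s, c = np.sin(pointing).sum(), np.cos(pointing).sum()
    mag = float(np.hypot(s, c))
    angle = math.degrees(math.atan2(s, c))
    pid = int(df["phase_id"].iloc[0]) if "phase_id" in df else (phase_id or 0)
    return AssimilatedVector(phase_id=pid,
                             angle=float(wrap_angle(angle - feeder_comb_angle)),
                             magnitude=mag)


def follower_mean_vector(phases) -> float:
    """Magnitude-weighted circular mean over a follower's phase vectors."""
    if len(phases) == 0:
        raise ValueError("need at least one phase vector")
    ang = np.radians([p.angle for p in phases])
    mag = np.array([p.magnitude for p in phases], dtype=float)
    s, c = (mag * np.sin(ang)).sum(), (mag * np.cos(ang)).sum()
    if np.hypot(s, c) < 1e-9:
        warnings.warn("total resultant ~0: mean vector undefined")
        return float("nan")
    return float(wrap_angle(math.degrees(math.atan2(s, c))))


def duration_to_distance(duration: float, slope: float = 1000.0,
                         intercept: float = 0.0) -> float:
    """Affine waggle-duration -> flight-distance map, in metres.

    The default slope (1000 m per second of waggling) and zero
    intercept are placeholders on the right order of magnitude for
    temperate *A. mellifera*; calibrate them for the colony at hand.
    """
    if duration < 0.05:
        raise ValueError("duration below the 0.05 s measurement floor")
    d = slope * duration + intercept
    if d < 0:
        warnings.warn("negative mapped distance clamped to 0")
        return 0.0
    return float(d)


def dancer_summary(dances: pd.DataFrame, bearings: pd.DataFrame,
                   feeder_comb_angle: float = 0.0) -> pd.DataFrame:
    """Join per-dancer dance precision with post-detour flight accuracy.

    ``dances`` needs columns (dancer_id, comb_angle_deg); ``bearings``
    needs (dancer_id, error_last_visible) — the signed post-detour
    error of the same individual.  Returns one row per dancer with the
    circular mean and s.d. of her waggle angles (as errors from the
    feeder's comb angle) next to the circular mean and s.d. of her
    flight errors.  Ids present on only one side are reported in the
    ``unmatched`` attribute rather than silently dropped.
    """
    rows = []
    d_ids = set(dances["dancer_id"])
    b_ids = set(bearings["dancer_id"])
    for did in sorted(d_ids & b_ids):
        ang = wrap_angle(dances.loc[dances["dancer_id"] == did,
                                    "comb_angle_deg"].to_numpy()
                         - feeder_comb_angle)
        mu_d, r_d = circ_mean_resultant(ang)
        errs = bearings.loc[bearings["dancer_id"] == did,
                            "error_last_visible"].to_numpy()
        errs = errs[np.isfinite(errs)]
        if errs.size == 0:
            continue
        mu_f, r_f = circ_mean_resultant(errs)
        rows.append({"dancer_id": did,
                     "n_phases": ang.size,
                     "dance_mean_error_deg": mu_d,
                     "dance_circ_sd_deg": circ_sd(r_d),
                     "n_flights": errs.size,
                     "flight_mean_error_deg": mu_f,
                     "flight_circ_sd_deg": circ_sd(r_f) if errs.size > 1
                     else 0.0 if r_f > 1 - 1e-12 else circ_sd(r_f)})
    out = pd.DataFrame(rows)
    out.attrs["unmatched"] = sorted(d_ids ^ b_ids)
    return out
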