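"""Synthetic detour-experiment data.

The real experiment films a bee leaving a detour tunnel against the sky
and separately films dances and dance followers in the hive.  This
module generates every input the analysis pipeline consumes — flight
trajectories, top-down video frames, waggle-phase records and follower
antennal traces — with the statistical structure the analysis assumes:

* intended flight bearings are von Mises-scattered around a target,
  with a configurable minority of "disoriented" bees whose intended
  bearing is uniform (emulating the observed >±90 deg deviants);
* after the detour exit, heading relaxes exponentially from the detour
  direction toward the intended bearing (the "immediate corrective
  turn" with a progressive per-boundary shift), with von Mises
  per-frame noise; tunnel flight speed averages 0.44 m/s;
* the flight camera runs at 60 Hz over a 1.56 m x 0.84 m plane, the
  hive camera at 80 Hz;
* waggle-phase angles are von Mises around the signalled comb angle,
  scattered enough that phases deviating >±60 deg from the target occur
  in most dances; durations are truncated-normal with a 0.05 s floor.

Trajectory coordinates are metres in an exit-centred, detour-aligned
frame: origin at the detour exit, +x along the detour heading, y
counterclockwise-positive.  A point's bearing atan2(y, x) is therefore
directly the flight angle relative to the detour, the quantity the
analysis measures.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import DetourConfig, shortcut_turn, wrap_angle
from .tracking import Trajectory

__all__ = [
    "FlightGenParams",
    "DanceGenParams",
    "VideoGenParams",
    "WagglePhase",
    "gen_flight",
    "gen_video",
    "write_frames",
    "gen_dance",
    "gen_follower_trace",
    "gen_cohort",
    "fov_bounds",
    "camera_for",
]

HIVE_FRAME_RATE = 80.0  # Hz, dance/follower camera
EXIT_OFFSET = (0.2, 0.0)  # exit position from the FOV's upstream edge centre, m


@dataclass
class FlightGenParams:
    """Population and dynamics parameters for post-detour flights."""

    intended_bearing_mean: float = 0.0  # deg rel. detour heading (the target)
    kappa_population: float = 3.0       # scatter of intended bearings over bees
    kappa_noise: float = 400.0          # per-frame heading jitter
    turn_rate: float = 2.0              # 1/s, exponential relaxation rate
    speed_mean: float = 0.44            # m/s, tunnel flight speed
    speed_sd: float = 0.05
    disoriented_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa_population < 0 or self.kappa_noise < 0:
            raise ValueError("kappa parameters must be >= 0")
        if not 0 <= self.disoriented_fraction <= 1:
            raise ValueError("disoriented_fraction must be in [0, 1]")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be positive")


@dataclass
class DanceGenParams:
    n_phases: int = 20
    comb_angle_mean: float = 0.0
    kappa_phase: float = 2.0      # wide scatter: >±60 deg deviants expected
    duration_mean: float = 0.45   # s; tunnel bees signal inflated distances
    duration_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.duration_mean <= 0:
            raise ValueError("durations must be positive")


@dataclass
class VideoGenParams:
    fov_length: float = 1.56
    fov_width: float = 0.84
    px_per_m: float = 200.0
    frame_rate: float = 60.0
    bee_radius_px: float = 6.0
    background_texture_seed: int = 0
    distractor_motion: bool = False
    exit_offset: tuple = EXIT_OFFSET  # exit from upstream-edge centre, m

    def __post_init__(self):
        if self.px_per_m <= 0:
            raise ValueError("px_per_m must be positive")
        if min(self.fov_length, self.fov_width) * self.px_per_m <= 2 * self.bee_radius_px:
            raise ValueError("field of view must exceed the bee blob")


@dataclass
class WagglePhase:
    """One waggle run: its comb angle, duration and (optional) raw thorax line."""

    phase_id: int
    comb_angle: float     # deg clockwise from gravity-up
    duration: float       # s, >= 0.05
    timestamp: object = None
    thorax_start: tuple = None
    thorax_end: tuple = None

    def __post_init__(self):
        if self.duration < 0.05:
            raise ValueError("duration below the 0.05 s measurement floor")
        self.comb_angle = wrap_angle(self.comb_angle)


def fov_bounds(p) -> tuple:
    """FOV rectangle (xmin, xmax, ymin, ymax) in the exit-centred frame.

    The exit sits ``p.exit_offset`` into the FOV from the upstream
    edge, centred across the width by default.
    """
    ex, ey = getattr(p, "exit_offset", EXIT_OFFSET)
    return (-ex, p.fov_length - ex, -p.fov_width / 2 - ey, p.fov_width / 2 - ey)


def _bee_rng(seed: int, bee_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(bee_id)]))


def camera_for(cfg: DetourConfig, lateral_shift: float = 0.25,
               **kwargs) -> VideoGenParams:
    """Camera placement for a detour condition.

    The field of view is aimed at the expected flight corridor: the
    exit sits 0.2 m inside the upstream edge and is shifted laterally
    *away* from the predicted shortcut side, so the 0.66 m boundary
    stays in view even for the +/-45 deg detours whose predicted turns
    approach +/-52 deg.  A 0 deg detour keeps the exit centred.
    """
    target = shortcut_turn(cfg)
    ey = lateral_shift * (1.0 if target < -1e-9 else -1.0 if target > 1e-9
                          else 0.0)
    return VideoGenParams(fov_length=cfg.fov_length, fov_width=cfg.fov_width,
                          frame_rate=cfg.frame_rate,
                          exit_offset=(EXIT_OFFSET[0], ey), **kwargs)


def gen_flight(cfg: DetourConfig, p: FlightGenParams, bee_id: int = 0,
               intended_bearing: float = None, fov_margin: float = 0.04
               ) -> Trajectory:
    """Simulate one post-detour flight in the exit-centred frame.

    The bee starts at the exit heading along the detour (bearing 0 in
    this frame).  Each frame her heading moves a fraction
    ``1 - exp(-turn_rate * dt)`` of the way toward her intended bearing,
    plus von Mises noise, and she advances at a (truncated) normal
    speed.  Frames are emitted until she leaves the field of view,
    shrunk by ``fov_margin`` so a rendered silhouette stays fully
    inside the frame up to the last emitted position.

    ``intended_bearing`` overrides the population draw (used when the
    cohort generator has already assigned it).
    """
    rng = _bee_rng(p.seed, bee_id)
    if intended_bearing is None:
        if rng.random() < p.disoriented_fraction:
            intended = rng.uniform(-180.0, 180.0)
        elif p.kappa_population > 1e8:
            intended = p.intended_bearing_mean
        else:
            intended = p.intended_bearing_mean + math.degrees(
                rng.vonmises(0.0, p.kappa_population))
    else:
        intended = float(intended_bearing)

    dt = 1.0 / cfg.frame_rate
    alpha = 1.0 - math.exp(-p.turn_rate * dt)
    vid = camera_for(cfg)
    xmin, xmax, ymin, ymax = fov_bounds(vid)
    xmin, xmax = xmin + fov_margin, xmax - fov_margin
    ymin, ymax = ymin + fov_margin, ymax - fov_margin

    max_frames = int(60 * cfg.frame_rate)  # hard cap: one minute of flight
    xs, ys = [0.0], [0.0]
    heading = 0.0  # detour heading in this frame
    x = y = 0.0
    for _ in range(max_frames):
        heading = heading + alpha * wrap_angle(intended - heading)
        if p.kappa_noise < 1e8:
            heading += math.degrees(rng.vonmises(0.0, p.kappa_noise)) if p.kappa_noise > 0 \
                else rng.uniform(-180.0, 180.0)
        heading = wrap_angle(heading)
        speed = max(rng.normal(p.speed_mean, p.speed_sd), 0.05 * p.speed_mean)
        x += speed * dt * math.cos(math.radians(heading))
        y += speed * dt * math.sin(math.radians(heading))
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            break
        xs.append(x)
        ys.append(y)
    if len(xs) < 2:
        raise ValueError("degenerate parameters: bee left the FOV immediately")
    frames = np.arange(len(xs))
    return Trajectory(bee_id=bee_id, frame_index=frames,
                      x=np.array(xs), y=np.array(ys),
                      frame_rate=cfg.frame_rate)


# --------------------------------------------------------------------------
# Video rendering
# --------------------------------------------------------------------------

def _texture(p: VideoGenParams, h: int, w: int) -> np.ndarray:
    rng = np.random.default_rng(p.background_texture_seed)
    # bright sky-like mottle: the bee is a dark silhouette against it
    return rng.integers(140, 255, size=(h, w)).astype(np.uint8)


def _to_px(p: VideoGenParams, x: float, y: float) -> tuple:
    """Exit-centred metres -> image pixels (origin top-left, y down)."""
    ex, ey = p.exit_offset
    px = (x + ex) * p.px_per_m
    py = (p.fov_width / 2 - ey - y) * p.px_per_m
    return px, py


def _stamp_blob(frame: np.ndarray, cx: float, cy: float, radius: float,
                value: int = 25) -> None:
    h, w = frame.shape
    x0, x1 = max(int(cx - radius) - 1, 0), min(int(cx + radius) + 2, w)
    y0, y1 = max(int(cy - radius) - 1, 0), min(int(cy + radius) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    frame[y0:y1, x0:x1][mask] = value


def gen_video(traj: Trajectory, p: VideoGenParams) -> np.ndarray:
    """Render a trajectory as a (n_frames, H, W) uint8 grayscale stack.

    Static textured background with a dark circular blob at each
    calibrated pixel position; with ``distractor_motion`` a second dark
    patch drifts along the far edge of the frame to stress the tracker's
    nearest-contour gating.
    """
    h = int(round(p.fov_width * p.px_per_m))
    w = int(round(p.fov_length * p.px_per_m))
    bg = _texture(p, h, w)
    xmin, xmax, ymin, ymax = fov_bounds(p)
    n = len(traj)
    frames = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        x, y = traj.x[i], traj.y[i]
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"trajectory leaves the FOV at frame {i}")
        frame = bg.copy()
        cx, cy = _to_px(p, x, y)
        _stamp_blob(frame, cx, cy, p.bee_radius_px)
        if p.distractor_motion:
            # drifting patch hugging the top edge, far from the bee
            dx = (i / max(n - 1, 1)) * (w - 20) + 10
            _stamp_blob(frame, dx, 6.0, 4.0, value=40)
        frames[i] = frame
    return frames


def write_frames(frames: np.ndarray, outdir, p: VideoGenParams,
                 traj: Trajectory = None) -> Path:
    """Write a PNG frame directory plus a YAML calibration sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:05d}.png", frame)
    ex, ey = p.exit_offset
    calib = {
        "px_per_m": p.px_per_m,
        "frame_rate": p.frame_rate,
        "exit_px": [float((0 + ex) * p.px_per_m),
                    float((p.fov_width / 2 - ey) * p.px_per_m)],
        "fov_length_m": p.fov_length,
        "fov_width_m": p.fov_width,
        "detour_normalised_east": True,
    }
    with open(outdir / "calibration.yaml", "w") as fh:
        yaml.safe_dump(calib, fh, sort_keys=False)
    return outdir


# --------------------------------------------------------------------------
# Dance-side generators
# --------------------------------------------------------------------------

def gen_dance(p: DanceGenParams) -> list:
    """Draw waggle phases: von Mises angles, truncated-normal durations."""
    rng = np.random.default_rng(p.seed)
    if p.kappa_phase > 1e8:
        angles = np.full(p.n_phases, p.comb_angle_mean)
    else:
        angles = p.comb_angle_mean + np.degrees(
            rng.vonmises(0.0, p.kappa_phase, size=p.n_phases)) \
            if p.kappa_phase > 0 else rng.uniform(-180, 180, size=p.n_phases)
    durations = rng.normal(p.duration_mean, p.duration_sd, size=p.n_phases)
    durations = np.maximum(np.round(durations / 0.05) * 0.05, 0.05)
    return [WagglePhase(phase_id=i, comb_angle=float(angles[i]),
                        duration=float(durations[i]))
            for i in range(p.n_phases)]


def gen_follower_trace(phases, follower_id: int = 0, heading_offset: float = 0.0,
                       antennal_spread: float = 60.0, noise_sd: float = 0.0,
                       seed: int = 0, frame_rate: float = HIVE_FRAME_RATE
                       ) -> pd.DataFrame:
    """Per-frame follower records consistent with the followed phases.

    During each phase the follower's body heading (relative to gravity)
    sits at ``heading_offset`` from the dance axis; her two antennae
    straddle the direction toward the dancer's instantaneous heading, so
    their circular midpoint plus her gravity heading recovers the dance
    angle.  Gaussian angular noise of ``noise_sd`` degrees is added
    independently to heading and each antenna.
    """
    if len(phases) == 0:
        raise ValueError("need at least one phase")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(follower_id)]))
    rows = []
    for ph in phases:
        n = max(int(round(ph.duration * frame_rate)), 2)
        for f in range(n):
            gravity = ph.comb_angle + heading_offset + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            mid_target = wrap_angle(ph.comb_angle - gravity)
            jl = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            jr = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({
                "follower_id": follower_id,
                "phase_id": ph.phase_id,
                "frame": f,
                "gravity_heading_deg": wrap_angle(gravity),
                "left_ant_deg": wrap_angle(mid_target + antennal_spread / 2 + jl),
                "right_ant_deg": wrap_angle(mid_target - antennal_spread / 2 + jr),
            })
    df = pd.DataFrame(rows)
    df.attrs["frame_rate"] = frame_rate
    return df


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

FORAGER_DETOURS = (-45.0, -30.0, 0.0, 30.0, 45.0)
RECRUIT_DETOURS = (-30.0, 0.0, 30.0)


def gen_cohort(cfg: DetourConfig, p: FlightGenParams, n_bees: int,
               seed: int = 0, exclusion_fraction: float = 0.0,
               recruit_fraction: float = 0.5,
               detour_angles: dict = None,
               aim: str = "shortcut") -> tuple:
    """Generate a cohort of flights plus per-bee metadata.

    Each bee gets a role (forager/recruit), a detour angle from its
    role's repertoire, a release timestamp, and an in-tunnel transit
    duration.  ``exclusion_fraction`` of bees are flagged for exclusion
    (half stopped in the tunnel, half with >30 s exits).  With
    ``aim="shortcut"`` the population's intended bearings are centred on
    each bee's shortcut target; ``aim="resume"`` centres them on the
    bearing-resume target (0 in the detour frame... i.e. -detour angle
    relative to it); a float centres them at that bearing directly.

    Returns ``(metadata DataFrame, {bee_id: Trajectory})``.
    """
    if n_bees < 1:
        raise ValueError("n_bees must be >= 1")
    if detour_angles is None:
        detour_angles = {"forager": FORAGER_DETOURS, "recruit": RECRUIT_DETOURS}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 917]))
    records, trajs = [], {}
    base = pd.Timestamp("2023-06-21 08:00:00", tz="UTC")
    for bee_id in range(n_bees):
        role = "recruit" if rng.random() < recruit_fraction else "forager"
        angle = float(rng.choice(detour_angles[role]))
        sub = replace(cfg, detour_relative_angle=angle)
        target = shortcut_turn(sub)
        if aim == "shortcut":
            centre = target
        elif aim == "resume":
            centre = float(wrap_angle(-angle))  # back onto the food compass bearing
        else:
            centre = float(aim)
        bee_params = replace(p, intended_bearing_mean=centre, seed=seed)
        traj = gen_flight(sub, bee_params, bee_id=bee_id)
        trajs[bee_id] = traj

        transit = sub.detour_length / max(rng.normal(p.speed_mean, p.speed_sd), 0.05)
        stopped = False
        if rng.random() < exclusion_fraction:
            if rng.random() < 0.5:
                stopped = True
            else:
                transit = 30.0 + rng.uniform(1.0, 30.0)
        records.append({
            "bee_id": bee_id,
            "role": role,
            "detour_angle_deg": angle,
            "target_angle_deg": target,
            "release_timestamp": base + pd.Timedelta(minutes=int(10 * bee_id)),
            "exit_duration_s": float(transit),
            "stopped": stopped,
        })
    meta = pd.DataFrame(records)
    return meta, trajs
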