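"""Recover flight trajectories from top-down video and convert them to
boundary-crossing bearings and speed estimates.

The flight camera records the bee's dark silhouette against the sky at
60 Hz.  A per-pixel Gaussian-mixture background model (Stauffer-Grimson
style, fully vectorised and deterministic) isolates moving pixels; the
connected foreground component nearest the bee's previous position
extends the trajectory.  Calibrated trajectories are then reduced to
the four angles the analysis uses: the bearing of the bee from the
detour exit when she first crosses circles of 0.22, 0.44 and 0.66 m,
and at her last visible position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .geometry import wrap_angle

__all__ = [
    "Calibration",
    "Trajectory",
    "BearingRecord",
    "MixtureBackgroundSubtractor",
    "track",
    "boundary_angles",
    "mean_speed",
    "apply_exclusions",
    "load_frames",
]


@dataclass
class Calibration:
    """Pixel<->metre mapping for a clip.

    Image pixels have origin top-left with y down; metric coordinates
    are exit-centred with y up and +x along the detour heading (videos
    are normalised so the detour runs along +x / "East").
    """

    px_per_m: float
    frame_rate: float
    exit_px: tuple  # (x, y) pixel position of the detour exit

    @classmethod
    def from_yaml(cls, path) -> "Calibration":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(px_per_m=float(raw["px_per_m"]),
                   frame_rate=float(raw["frame_rate"]),
                   exit_px=tuple(raw["exit_px"]))

    def px_to_m(self, px: np.ndarray, py: np.ndarray) -> tuple:
        x = (np.asarray(px, float) - self.exit_px[0]) / self.px_per_m
        y = (self.exit_px[1] - np.asarray(py, float)) / self.px_per_m
        return x, y


@dataclass
class Trajectory:
    """Time-ordered 2-D positions in metres (exit-centred, y up)."""

    bee_id: int
    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    lost_track: bool = False

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frame_index) == len(self.x) == len(self.y)):
            raise ValueError("frame/coordinate lengths differ")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must strictly increase")

    def __len__(self):
        return len(self.frame_index)

    @property
    def times(self) -> np.ndarray:
        return self.frame_index / self.frame_rate

    def to_csv(self, path) -> None:
        pd.DataFrame({"bee_id": self.bee_id, "frame": self.frame_index,
                      "x_m": self.x, "y_m": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(bee_id=int(df["bee_id"].iloc[0]), frame_index=df["frame"],
                   x=df["x_m"], y=df["y_m"], frame_rate=frame_rate)


@dataclass
class BearingRecord:
    """Per-bee angles at each boundary plus the last visible position.

    Angles are degrees relative to the detour heading, CCW positive,
    wrapped to (-180, 180]; a boundary the bee never crossed is NaN.
    ``signed_errors`` are wrap(angle - target) per boundary then last
    visible (positive = left of target).
    """

    bee_id: int
    boundary_radii: tuple
    boundary_angles: tuple      # deg, NaN where the boundary was not crossed
    angle_last_visible: float
    target_angle: float = float("nan")
    signed_errors: tuple = None
    exit_duration: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if self.signed_errors is None and np.isfinite(self.target_angle):
            angles = list(self.boundary_angles) + [self.angle_last_visible]
            self.signed_errors = tuple(
                float(wrap_angle(a - self.target_angle)) if np.isfinite(a)
                else float("nan") for a in angles)

    def to_dict(self):
        d = {"bee_id": self.bee_id, "target_angle": self.target_angle,
             "angle_last_visible": self.angle_last_visible,
             "exit_duration": self.exit_duration, "excluded": self.excluded,
             "exclusion_reason": self.exclusion_reason}
        for i, (r, a) in enumerate(zip(self.boundary_radii, self.boundary_angles)):
            d[f"angle_at_r{i + 1}"] = a
        if self.signed_errors is not None:
            for i, e in enumerate(self.signed_errors[:-1]):
                d[f"error_at_r{i + 1}"] = e
            d["error_last_visible"] = self.signed_errors[-1]
        return d


# --------------------------------------------------------------------------
# Background subtraction + tracking
# --------------------------------------------------------------------------

class MixtureBackgroundSubtractor:
    """Per-pixel Gaussian-mixture background model for grayscale video.

    K Gaussians per pixel with weights, means and variances updated
    online (Stauffer & Grimson 1999).  A pixel is foreground when its
    value matches none of the high-weight "background" components.
    Deterministic: identical frame sequences give identical masks.
    """

    def __init__(self, n_components: int = 3, learning_rate: float = 0.05,
                 match_sigma: float = 2.5, background_ratio: float = 0.7,
                 initial_var: float = 225.0):
        self.k = n_components
        self.lr = learning_rate
        self.match_sigma = match_sigma
        self.background_ratio = background_ratio
        self.initial_var = initial_var
        self._init = False

    def _initialise(self, frame: np.ndarray) -> None:
        h, w = frame.shape
        self.mu = np.zeros((self.k, h, w))
        self.var = np.full((self.k, h, w), self.initial_var)
        self.wgt = np.zeros((self.k, h, w))
        self.mu[0] = frame
        self.wgt[0] = 1.0
        self._init = True

    def initialise_from(self, frames) -> None:
        """Seed the dominant component with the pixel-wise clip median.

        Clips are shorter than a second, so the whole history is
        available up front; the median excises the moving bee from the
        background estimate and avoids warm-up ghosting around her
        first position.
        """
        med = np.median(np.asarray(frames, dtype=float), axis=0)
        self._initialise(med)

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Update the model with one frame; return the foreground mask."""
        frame = np.asarray(frame, dtype=float)
        if not self._init:
            self._initialise(frame)
            return np.zeros(frame.shape, dtype=bool)

        dist2 = (frame[None] - self.mu) ** 2
        match = dist2 <= (self.match_sigma ** 2) * self.var
        # each pixel matches at most its best (highest weight/sigma) component
        fitness = self.wgt / np.sqrt(self.var)
        fitness_masked = np.where(match, fitness, -np.inf)
        best = np.argmax(fitness_masked, axis=0)
        any_match = match.any(axis=0)
        sel = np.zeros_like(match)
        np.put_along_axis(sel, best[None], any_match[None], axis=0)

        # weight update, then mean/variance of the matched component
        self.wgt = (1 - self.lr) * self.wgt + self.lr * sel
        rho = self.lr / np.maximum(self.wgt, 1e-6)
        upd = sel.astype(float)
        self.mu += upd * rho * (frame[None] - self.mu)
        self.var += upd * rho * (dist2 - self.var)
        self.var = np.clip(self.var, 4.0, 1e4)

        # unmatched pixels: replace the weakest component
        weakest = np.argmin(self.wgt, axis=0)
        repl = ~any_match
        if repl.any():
            rr = np.zeros_like(sel)
            np.put_along_axis(rr, weakest[None], repl[None], axis=0)
            self.mu = np.where(rr, frame[None], self.mu)
            self.var = np.where(rr, self.initial_var, self.var)
            self.wgt = np.where(rr, 0.05, self.wgt)
        self.wgt /= self.wgt.sum(axis=0, keepdims=True)

        # background = top components holding background_ratio of the weight
        order = np.argsort(-self.wgt, axis=0)
        wsort = np.take_along_axis(self.wgt, order, axis=0)
        cum = np.cumsum(wsort, axis=0)
        is_bg_sorted = (cum - wsort) < self.background_ratio
        is_bg = np.zeros_like(is_bg_sorted)
        np.put_along_axis(is_bg, order, is_bg_sorted, axis=0)
        fg = ~(match & is_bg).any(axis=0)
        return fg


def _contour_centres(mask: np.ndarray, min_area: int = 4) -> np.ndarray:
    """Centres (x_px, y_px) of connected foreground components."""
    lbl, n = ndimage.label(mask)
    if n == 0:
        return np.empty((0, 2))
    areas = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
    keep = [i + 1 for i, a in enumerate(areas) if a >= min_area]
    if not keep:
        return np.empty((0, 2))
    centres = ndimage.center_of_mass(mask, lbl, keep)  # (row, col)
    return np.array([(c, r) for r, c in centres])


def track(frames, initial_position, calibration: Calibration = None,
          gating_radius_px: float = 30.0, bee_id: int = 0,
          min_area: int = 4) -> "Trajectory | list":
    """Track a single bee through a frame stack.

    ``initial_position`` is the bee's first visible pixel position
    (x, y).  The background model is seeded from the whole clip's
    pixel-wise median; in each frame the foreground contour centre
    nearest the previous position (within ``gating_radius_px``)
    extends the track.  If no contour
    falls inside the gate the partial trajectory is returned with
    ``lost_track=True`` rather than failing, so a manual override
    workflow remains possible.

    With a ``calibration`` the result is a metric :class:`Trajectory`;
    without one, a list of (frame, x_px, y_px).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a (n_frames, H, W) stack with n >= 2")
    h, w = frames.shape[1:]
    x0, y0 = initial_position
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("initial position outside the frame")

    sub = MixtureBackgroundSubtractor()
    sub.initialise_from(frames)
    prev = np.array([x0, y0], dtype=float)
    points, lost = [], False
    for i, frame in enumerate(frames):
        mask = sub.apply(frame)
        centres = _contour_centres(mask, min_area=min_area)
        if len(centres) == 0:
            if i == 0:
                # nothing moving yet: trust the operator's initial click
                points.append((i, float(x0), float(y0)))
                continue
            lost = True
            break
        d = np.linalg.norm(centres - prev, axis=1)
        j = int(np.argmin(d))
        if d[j] > gating_radius_px:
            lost = True
            break
        prev = centres[j]
        points.append((i, float(prev[0]), float(prev[1])))
    if not points:
        raise ValueError("no foreground found near the initial position")

    if calibration is None:
        return points if not lost else points
    fi = np.array([p[0] for p in points])
    px = np.array([p[1] for p in points])
    py = np.array([p[2] for p in points])
    xm, ym = calibration.px_to_m(px, py)
    return Trajectory(bee_id=bee_id, frame_index=fi, x=xm, y=ym,
                      frame_rate=calibration.frame_rate, lost_track=lost)


def load_frames(directory) -> np.ndarray:
    """Load a PNG frame directory (sorted by name) as a uint8 stack."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG frames under {directory}")
    return np.stack([iio.imread(p) for p in paths])


# --------------------------------------------------------------------------
# Boundary bearings, speed, exclusions
# --------------------------------------------------------------------------

def boundary_angles(traj: Trajectory, exit_position=(0.0, 0.0),
                    radii=(0.22, 0.44, 0.66), target_angle: float = float("nan"),
                    exit_duration: float = float("nan"),
                    interpolate: bool = False) -> BearingRecord:
    """Bearings of the bee from the detour exit at each boundary crossing.

    For each radius r the angle is taken at the *first* frame whose
    distance from the exit reaches r (no sub-frame interpolation by
    default, matching the frame-based measurement); the last visible
    angle comes from the final tracked position.  Boundaries never
    reached are NaN.
    """
    ex, ey = exit_position
    dx, dy = traj.x - ex, traj.y - ey
    dist = np.hypot(dx, dy)
    if dist.max() < 0.01:
        raise ValueError("bee never left a 1 cm neighbourhood of the exit")
    bearings = np.degrees(np.arctan2(dy, dx))

    out = []
    for r in radii:
        idx = np.nonzero(dist >= r)[0]
        if idx.size == 0:
            out.append(float("nan"))
            continue
        i = int(idx[0])
        if interpolate and i > 0 and dist[i] > dist[i - 1]:
            f = (r - dist[i - 1]) / (dist[i] - dist[i - 1])
            x = dx[i - 1] + f * (dx[i] - dx[i - 1])
            y = dy[i - 1] + f * (dy[i] - dy[i - 1])
            out.append(float(wrap_angle(math.degrees(math.atan2(y, x)))))
        else:
            out.append(float(wrap_angle(bearings[i])))
    last = float(wrap_angle(bearings[-1]))
    return BearingRecord(bee_id=traj.bee_id, boundary_radii=tuple(radii),
                         boundary_angles=tuple(out), angle_last_visible=last,
                         target_angle=float(target_angle),
                         exit_duration=exit_duration)


def mean_speed(traj: Trajectory, window: float = 0.2,
               start_fraction: float = 0.4) -> float:
    """Mean speed over a distance window in the midsection of the path.

    Measures the time to travel ``window`` metres of arc length
    starting at ``start_fraction`` of the total path length, avoiding
    the initial acceleration.  Time resolution is inherently one frame
    period (1/60 s at the default rate).
    """
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    total = arc[-1]
    start = start_fraction * total
    if total - start < window:
        start = total - window
    if start < 0 or total < window:
        raise ValueError(f"trajectory covers {total:.3f} m < {window} m window")
    i0 = int(np.searchsorted(arc, start))
    i1 = int(np.searchsorted(arc, arc[i0] + window))
    if i1 >= len(arc):
        raise ValueError("window not fully covered by the trajectory")
    dt = (traj.frame_index[i1] - traj.frame_index[i0]) / traj.frame_rate
    if dt <= 0:
        raise ValueError("zero elapsed time over the window")
    return float((arc[i1] - arc[i0]) / dt)


def apply_exclusions(records, max_exit_duration: float = 30.0,
                     stopped_flags=None) -> tuple:
    """Partition bearing records into retained and excluded sets.

    A record is excluded when the bee stopped flying in the tunnel or
    took strictly longer than ``max_exit_duration`` seconds to exit
    (exactly 30.0 s is retained).  Returns ``(retained, excluded)``
    lists; each excluded record carries its reason.
    """
    retained, excluded = [], []
    for i, rec in enumerate(records):
        stopped = stopped_flags[i] if stopped_flags is not None else getattr(
            rec, "stopped", False)
        if not np.isfinite(rec.exit_duration):
            raise ValueError(f"record {rec.bee_id}: missing exit duration")
        if stopped:
            rec.excluded, rec.exclusion_reason = True, "stopped_in_tunnel"
            excluded.append(rec)
        elif rec.exit_duration > max_exit_duration:
            rec.excluded, rec.exclusion_reason = True, "exit_over_30s"
            excluded.append(rec)
        else:
            rec.excluded, rec.exclusion_reason = False, ""
            retained.append(rec)
    return retained, excluded
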