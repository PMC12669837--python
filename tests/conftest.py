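import numpy as np
import pytest
from hypothesis import settings

from beevector.geometry import DetourConfig, shortcut_turn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from beevector.synthetic import FlightGenParams, VideoGenParams, camera_for


@pytest.fixture
def cfg45():
    """The canonical training condition with a +45 deg detour."""
    return DetourConfig(detour_relative_angle=45.0)


@pytest.fixture
def cfg30():
    return DetourConfig(detour_relative_angle=30.0)


@pytest.fixture
def noise_free_params(cfg45):
    """Flight params whose only motion is deterministic relaxation."""
    return FlightGenParams(intended_bearing_mean=shortcut_turn(cfg45),
                           kappa_population=1e12, kappa_noise=1e12,
                           speed_sd=0.0, seed=0)


def make_tracked(cfg, params, bee_id=0, **video_kwargs):
    """gen_flight -> gen_video -> track with a consistent calibration."""
    from beevector.synthetic import _to_px, gen_flight, gen_video
    from beevector.tracking import Calibration, track

    traj = gen_flight(cfg, params, bee_id=bee_id)
    vid = camera_for(cfg, **video_kwargs)
    frames = gen_video(traj, vid)
    calib = Calibration(px_per_m=vid.px_per_m, frame_rate=vid.frame_rate,
                        exit_px=_to_px(vid, 0.0, 0.0))
    tracked = track(frames, _to_px(vid, traj.x[0], traj.y[0]),
                    calibration=calib, bee_id=bee_id)
    return traj, tracked
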