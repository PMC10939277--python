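"""Deterministic trial geometry for the lateral-motion VR paradigm.

The observer stands still or translates laterally while a ball travels
laterally at a constant speed 8 m in front of them.  The ball is visible for
0.5 s and then occluded; the target sits at the distance the ball covers
during the occlusion interval.  Self-motion ramps on over the first 50 ms,
holds a 4 m/s plateau for 400 ms, and ramps off over the last 50 ms, so the
observer covers 1.8 m in 0.5 s (time-averaged speed 3.6 m/s).

Everything here is noise-free: these routines define the stimulus, not the
percept.  Angles are measured from the translating observer's fixed
straight-ahead direction (head rotation is assumed zero, matching the
fixation instruction), positive in the ball's travel direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.special import ndtr

__all__ = [
    "SelfMotionProfile",
    "TrialGeometry",
    "RetinalTrace",
    "self_speed_at",
    "observer_displacement",
    "target_distance",
    "retinal_trace",
    "mean_abs_retinal_speed",
    "BALL_SPEEDS",
    "MAIN_OCCLUSIONS",
    "EXTRA_STATIC_OCCLUSIONS",
    "PROFILES",
]

BALL_SPEEDS = (4.0, 5.0, 6.0)
MAIN_OCCLUSIONS = (0.5, 0.6, 0.7)
EXTRA_STATIC_OCCLUSIONS = (0.1, 0.2, 0.3, 0.4, 0.8, 0.9, 1.0)
PROFILES = ("static", "same", "opposite")

# Gaussian-CDF ramp support: the ramp spans +-_RAMP_SIGMAS standard
# deviations, and the raw CDF is renormalised to hit exactly 0 and 1 at the
# ramp edges.  Any value >= 3 gives visually indistinguishable ramps; the
# renormalisation keeps the point symmetry that forces each ramp to average
# exactly half of the plateau speed.
_RAMP_SIGMAS = 3.0


@dataclass(frozen=True)
class SelfMotionProfile:
    """Ramped lateral self-motion speed profile.

    ``direction`` is relative to the ball's travel direction: ``same`` moves
    the observer with the ball, ``opposite`` against it, ``static`` not at
    all.  With the defaults a non-static profile covers 1.8 m over the
    0.5 s trial (mean speed 3.6 m/s).
    """

    direction: str = "static"
    peak_speed: float = 4.0
    ramp_duration: float = 0.05
    steady_duration: float = 0.40
    total_duration: float = 0.50
    ramp_shape: str = "gaussian_cdf"

    def __post_init__(self) -> None:
        if self.direction not in PROFILES:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.ramp_shape not in ("gaussian_cdf", "linear"):
            raise ValueError(f"unknown ramp_shape {self.ramp_shape!r}")
        for name in ("peak_speed", "ramp_duration", "steady_duration", "total_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not np.isclose(2 * self.ramp_duration + self.steady_duration, self.total_duration):
            raise ValueError("total_duration must equal steady_duration + 2*ramp_duration")

    @property
    def sign(self) -> int:
        """Signed direction on the lateral axis (positive = ball direction)."""
        return {"static": 0, "same": 1, "opposite": -1}[self.direction]

    @property
    def mean_speed(self) -> float:
        """Time-averaged speed over the full profile (3.6 m/s at defaults)."""
        if self.direction == "static":
            return 0.0
        moving = self.steady_duration + self.ramp_duration  # each ramp averages peak/2
        return self.peak_speed * moving / self.total_duration


def _ramp_fraction(u: np.ndarray, shape: str) -> np.ndarray:
    """Normalised ramp shape on u in [0, 1], 0 at u=0 and 1 at u=1.

    Both shapes are point-symmetric about (1/2, 1/2), so the ramp mean is
    exactly 1/2 -- the property that pins total displacement to 1.8 m.
    """
    if shape == "linear":
        return u
    z = (u - 0.5) * 2 * _RAMP_SIGMAS
    lo = ndtr(-_RAMP_SIGMAS)
    return (ndtr(z) - lo) / (1.0 - 2.0 * lo)


def self_speed_at(profile: SelfMotionProfile, t) -> np.ndarray | float:
    """Unsigned self-motion speed (m/s) at time ``t`` (scalar or array)."""
    scalar = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    if profile.direction != "static":
        r, total = profile.ramp_duration, profile.total_duration
        inside = (t_arr > 0) & (t_arr < total)
        tt = t_arr[inside]
        frac = np.ones_like(tt)
        if r > 0:
            up = tt < r
            down = tt > total - r
            frac[up] = _ramp_fraction(tt[up] / r, profile.ramp_shape)
            frac[down] = _ramp_fraction((total - tt[down]) / r, profile.ramp_shape)
        out[inside] = profile.peak_speed * frac
    return float(out[0]) if scalar else out


def observer_displacement(profile: SelfMotionProfile, t0: float, t1: float) -> float:
    """Signed lateral observer displacement (m) between ``t0`` and ``t1``.

    Positive along the ball's travel direction; an ``opposite`` profile
    therefore yields negative displacement.
    """
    if t0 > t1:
        raise ValueError("t0 must not exceed t1")
    if profile.direction == "static":
        return 0.0
    r, total = profile.ramp_duration, profile.total_duration
    breaks = [b for b in (0.0, r, total - r, total) if t0 < b < t1]
    area, _ = quad(
        lambda t: self_speed_at(profile, t),
        t0,
        t1,
        points=breaks or None,
        limit=200,
        epsabs=1e-12,
        epsrel=1e-12,
    )
    return profile.sign * area


def target_distance(occlusion_duration: float, ball_speed: float) -> float:
    """Occluded distance (m): the exact product of duration and ball speed."""
    if occlusion_duration <= 0 or ball_speed <= 0:
        raise ValueError("occlusion_duration and ball_speed must be positive")
    return occlusion_duration * ball_speed


@dataclass(frozen=True)
class TrialGeometry:
    """One trial's deterministic stimulus parameters."""

    ball_speed: float
    occlusion_duration: float
    ball_direction: str = "right"
    depth: float = 8.0
    visible_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.ball_speed <= 0 or self.occlusion_duration <= 0:
            raise ValueError("ball_speed and occlusion_duration must be positive")
        if self.depth <= 0 or self.visible_duration <= 0:
            raise ValueError("depth and visible_duration must be positive")
        if self.ball_direction not in ("left", "right"):
            raise ValueError("ball_direction must be 'left' or 'right'")

    @property
    def occluded_distance(self) -> float:
        return target_distance(self.occlusion_duration, self.ball_speed)


@dataclass(frozen=True)
class RetinalTrace:
    """Angular position/speed of the ball over the visible window."""

    times: np.ndarray
    angle_deg: np.ndarray
    angular_speed_degps: np.ndarray


def retinal_trace(
    geom: TrialGeometry, profile: SelfMotionProfile, dt: float = 1e-3
) -> RetinalTrace:
    """Retinal eccentricity and angular speed of the ball while visible.

    The visible path is centred on the observer's starting straight-ahead:
    the ball's lateral position runs from -v*T/2 to +v*T/2 along its travel
    axis.  The observer translates according to ``profile``; the angle is
    arctan(relative lateral offset / depth), signed positive toward the
    ball's travel direction (mirrored for a leftward ball).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.005:
        raise ValueError("dt must be at most 5 ms for an accurate derivative")
    T = geom.visible_duration
    n = int(round(T / dt))
    times = np.linspace(0.0, T, n + 1)
    ball_x = -geom.ball_speed * T / 2 + geom.ball_speed * times
    speeds = self_speed_at(profile, times)
    obs_x = profile.sign * np.concatenate(
        ([0.0], cumulative_trapezoid(speeds, times))
    )
    angle = np.degrees(np.arctan2(ball_x - obs_x, geom.depth))
    if geom.ball_direction == "left":
        angle = -angle
    ang_speed = np.gradient(angle, times)
    return RetinalTrace(times=times, angle_deg=angle, angular_speed_degps=ang_speed)


def mean_abs_retinal_speed(
    geom: TrialGeometry, profile: SelfMotionProfile, dt: float = 1e-3
) -> float:
    """Time-averaged absolute retinal speed (deg/s) over the visible window."""
    tr = retinal_trace(geom, profile, dt)
    return float(np.trapezoid(np.abs(tr.angular_speed_degps), tr.times) / tr.times[-1])


def retinal_speed_table(dt: float = 1e-3) -> "np.ndarray":
    """3x3 mean |retinal speed| table over profiles x ball speeds.

    Rows follow ``PROFILES``; columns follow ``BALL_SPEEDS``.  Occlusion
    duration does not matter for the visible window; a placeholder is used.
    """
    out = np.empty((len(PROFILES), len(BALL_SPEEDS)))
    for i, prof in enumerate(PROFILES):
        p = SelfMotionProfile(direction=prof)
        for j, v in enumerate(BALL_SPEEDS):
            g = TrialGeometry(ball_speed=v, occlusion_duration=0.5)
            out[i, j] = mean_abs_retinal_speed(g, p, dt)
    return out
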