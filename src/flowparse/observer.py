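"""Generative observer model and synthetic-data generator for both tasks.

The model formalises incomplete flow parsing: when the observer translates
while watching the ball, a fraction of the self-motion speed is wrongly
attributed to the ball.  Perceived ball speed is

    v_perceived ~ N(v_ball + bias(profile) * v_self,
                    weber_speed * mean * (1 + precision(profile)))

with ``v_self`` the nominal (time-averaged) self-motion speed of 3.6 m/s.
Biases and precision effects apply to the Opposite Directions profile (and
optionally Same Direction); the static profile is unbiased.  In the
prediction task the occluded distance is perceived with its own Weber
fraction and the button press happens at the extrapolated time

    t_extrapolated = d_perceived / v_perceived.

In the 2IFC speed task the ball-cloud interval carries no self-motion, so
its percept is unbiased with the same speed Weber fraction; the choice is a
straight comparison of the two percept samples.

Population defaults are the study's generative assumptions: a 20% bias of
self-motion speed (between-participant SD 30%), a 20% precision effect
(SD 30%), a 10% speed Weber fraction (SD 1.5%) and a 5% distance Weber
fraction (common to all participants).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import pest
from .kinematics import (
    BALL_SPEEDS,
    EXTRA_STATIC_OCCLUSIONS,
    MAIN_OCCLUSIONS,
    PROFILES,
    SelfMotionProfile,
    TrialGeometry,
)

__all__ = [
    "PopulationSpec",
    "ObserverParams",
    "PerceptSample",
    "PredictionDesign",
    "SpeedDesign",
    "draw_observer",
    "draw_observers",
    "perceived_speed_sample",
    "simulate_prediction_trial",
    "simulate_prediction_experiment",
    "simulate_2ifc_trial",
    "simulate_speed_experiment",
    "PERCEPT_FLOOR",
]

#: Perceived speeds are resampled until they exceed this floor (m/s) so the
#: extrapolation ratio cannot blow up; the perceptual model itself is silent
#: on zero or negative percepts.
PERCEPT_FLOOR = 0.1
_DISTANCE_FLOOR = 0.01  # m; same role for perceived distance
_WEBER_FLOOR = 0.01
_PRECISION_FLOOR = -0.9


@dataclass(frozen=True)
class PopulationSpec:
    """Between-participant distribution of observer parameters."""

    bias_mean: float = 0.20
    bias_sd: float = 0.30
    precision_effect_mean: float = 0.20
    precision_effect_sd: float = 0.30
    bias_same_mean: float = 0.0
    bias_same_sd: float = 0.0
    precision_same_mean: float = 0.0
    precision_same_sd: float = 0.0
    weber_speed_mean: float = 0.10
    weber_speed_sd: float = 0.015
    weber_distance: float = 0.05
    nominal_self_speed: float = 3.6

    def __post_init__(self) -> None:
        for name in (
            "bias_sd",
            "precision_effect_sd",
            "bias_same_sd",
            "precision_same_sd",
            "weber_speed_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.weber_distance < 0:
            raise ValueError("weber_distance must be non-negative")
        if self.nominal_self_speed <= 0:
            raise ValueError("nominal_self_speed must be positive")

    @classmethod
    def null(cls, **overrides) -> "PopulationSpec":
        """All self-motion effects switched off (false-positive-rate runs)."""
        return cls(
            bias_mean=0.0,
            bias_sd=0.0,
            precision_effect_mean=0.0,
            precision_effect_sd=0.0,
            **overrides,
        )


@dataclass(frozen=True)
class ObserverParams:
    """One simulated participant."""

    participant_id: int
    bias_opposite: float
    bias_same: float = 0.0
    precision_opposite: float = 0.0
    precision_same: float = 0.0
    weber_speed: float = 0.10
    weber_distance: float = 0.05

    def __post_init__(self) -> None:
        if self.weber_speed <= 0:
            raise ValueError("weber_speed must be positive")
        if min(self.precision_opposite, self.precision_same) <= -1:
            raise ValueError("precision effects must exceed -1")

    def bias(self, profile: str) -> float:
        return {"static": 0.0, "same": self.bias_same, "opposite": self.bias_opposite}[profile]

    def precision(self, profile: str) -> float:
        return {
            "static": 0.0,
            "same": self.precision_same,
            "opposite": self.precision_opposite,
        }[profile]


@dataclass(frozen=True)
class PerceptSample:
    """Percepts underlying one prediction-task trial."""

    v_perceived: float
    d_perceived: float

    @property
    def t_extrapolated(self) -> float:
        return self.d_perceived / self.v_perceived


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Gaussian draw(s) resampled until strictly above ``lower``."""
    x = rng.normal(mean, sd, size)
    if size is None:
        while x <= lower:
            x = rng.normal(mean, sd)
        return float(x)
    mean_b = np.broadcast_to(np.asarray(mean, dtype=float), x.shape)
    sd_b = np.broadcast_to(np.asarray(sd, dtype=float), x.shape)
    bad = x <= lower
    while bad.any():
        x[bad] = rng.normal(mean_b[bad], sd_b[bad])
        bad = x <= lower
    return x


def draw_observer(pop: PopulationSpec, rng: np.random.Generator, participant_id: int = 0) -> ObserverParams:
    """Draw one participant's parameters from the population."""
    return ObserverParams(
        participant_id=participant_id,
        bias_opposite=float(rng.normal(pop.bias_mean, pop.bias_sd)),
        bias_same=float(rng.normal(pop.bias_same_mean, pop.bias_same_sd)),
        precision_opposite=_truncated_normal(
            rng, pop.precision_effect_mean, pop.precision_effect_sd, _PRECISION_FLOOR
        ),
        precision_same=_truncated_normal(
            rng, pop.precision_same_mean, pop.precision_same_sd, _PRECISION_FLOOR
        ),
        weber_speed=_truncated_normal(rng, pop.weber_speed_mean, pop.weber_speed_sd, _WEBER_FLOOR),
        weber_distance=pop.weber_distance,
    )


def perceived_speed_mean_sd(
    v_ball: float, profile: str, obs: ObserverParams, nominal_self_speed: float
) -> tuple[float, float]:
    """Mean and SD of the perceived ball speed in a given motion profile."""
    mean = v_ball + obs.bias(profile) * nominal_self_speed
    sd = obs.weber_speed * mean * (1.0 + obs.precision(profile))
    return mean, abs(sd)


def perceived_speed_sample(
    v_ball: float,
    profile: str | SelfMotionProfile,
    obs: ObserverParams,
    nominal_self_speed: float,
    rng: np.random.Generator,
    size=None,
):
    """Sample perceived ball speed(s); resampled to stay above the floor."""
    if v_ball <= 0:
        raise ValueError("v_ball must be positive")
    direction = profile.direction if isinstance(profile, SelfMotionProfile) else profile
    mean, sd = perceived_speed_mean_sd(v_ball, direction, obs, nominal_self_speed)
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    return _truncated_normal(rng, mean, sd, PERCEPT_FLOOR, size)


def simulate_prediction_trial(
    geom: TrialGeometry,
    profile: str | SelfMotionProfile,
    obs: ObserverParams,
    pop: PopulationSpec,
    rng: np.random.Generator,
) -> dict:
    """One prediction-task trial: percepts, button-press time, timing error."""
    direction = profile.direction if isinstance(profile, SelfMotionProfile) else profile
    d = geom.occluded_distance
    if obs.weber_distance > 0:
        d_perc = _truncated_normal(rng, d, obs.weber_distance * d, _DISTANCE_FLOOR)
    else:
        d_perc = d
    v_perc = perceived_speed_sample(geom.ball_speed, direction, obs, pop.nominal_self_speed, rng)
    response = d_perc / v_perc
    return {
        "participant_id": obs.participant_id,
        "ball_speed_mps": geom.ball_speed,
        "motion_profile": direction,
        "occlusion_s": geom.occlusion_duration,
        "response_s": response,
        "error_s": response - geom.occlusion_duration,
        "v_perceived_mps": v_perc,
        "d_perceived_m": d_perc,
    }


@dataclass(frozen=True)
class PredictionDesign:
    """Factorial layout of the prediction task.

    The main design crosses ball speeds, motion profiles and occlusion
    durations; the extra occlusion durations run with a static observer
    only.  ``repetitions`` is explicit because it is the design's main
    dial (5/9/13 in the power grid).
    """

    n_participants: int = 40
    repetitions: int = 13
    speeds: Sequence[float] = BALL_SPEEDS
    profiles: Sequence[str] = PROFILES
    occlusions: Sequence[float] = MAIN_OCCLUSIONS
    extra_static_occlusions: Sequence[float] = EXTRA_STATIC_OCCLUSIONS
    include_static_extra: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.repetitions < 1:
            raise ValueError("n_participants and repetitions must be positive")
        if not (self.speeds and self.profiles and self.occlusions):
            raise ValueError("design must list speeds, profiles and occlusions")

    def cells(self) -> pd.DataFrame:
        """One row per condition cell (before repetitions)."""
        main = [
            (v, p, o)
            for v in self.speeds
            for p in self.profiles
            for o in self.occlusions
        ]
        if self.include_static_extra:
            main += [(v, "static", o) for v in self.speeds for o in self.extra_static_occlusions]
        return pd.DataFrame(main, columns=["ball_speed_mps", "motion_profile", "occlusion_s"])

    @property
    def trials_per_participant(self) -> int:
        return len(self.cells()) * self.repetitions


def draw_observers(pop: PopulationSpec, n: int, rng) -> list[ObserverParams]:
    """Draw a cohort; reuse the list across tasks to share participants."""
    return [draw_observer(pop, rng, participant_id=i) for i in range(n)]


_draw_observers = draw_observers  # internal alias


def simulate_prediction_experiment(
    design: PredictionDesign,
    pop: PopulationSpec,
    rng: np.random.Generator | int | None = None,
    observers: Sequence[ObserverParams] | None = None,
) -> pd.DataFrame:
    """Simulate the full prediction task for a cohort.

    Returns the trial table (``participant_id``, ``ball_speed_mps``,
    ``motion_profile``, ``occlusion_s``, ``response_s``, ``error_s``).
    Observer parameters may be supplied to reuse a cohort across tasks.
    """
    rng = np.random.default_rng(rng)
    if observers is None:
        observers = _draw_observers(pop, design.n_participants, rng)
    cells = design.cells()
    reps = design.repetitions
    n_cells = len(cells)

    frames = []
    v = np.repeat(cells["ball_speed_mps"].to_numpy(), reps)
    prof = np.repeat(cells["motion_profile"].to_numpy(), reps)
    occ = np.repeat(cells["occlusion_s"].to_numpy(), reps)
    d = occ * v
    for obs in observers:
        bias = np.array([obs.bias(p) for p in prof])
        prec = np.array([obs.precision(p) for p in prof])
        mean = v + bias * pop.nominal_self_speed
        sd = np.abs(obs.weber_speed * mean * (1.0 + prec))
        v_perc = _truncated_normal(rng, mean, sd, PERCEPT_FLOOR, size=n_cells * reps)
        d_perc = _truncated_normal(
            rng, d, obs.weber_distance * d, _DISTANCE_FLOOR, size=n_cells * reps
        ) if obs.weber_distance > 0 else d
        response = d_perc / v_perc
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": obs.participant_id,
                    "ball_speed_mps": v,
                    "motion_profile": prof,
                    "occlusion_s": occ,
                    "response_s": response,
                    "error_s": response - occ,
                    "v_perceived_mps": v_perc,
                    "d_perceived_m": d_perc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_2ifc_trial(
    v_ball: float,
    cloud_speed: float,
    profile: str | SelfMotionProfile,
    obs: ObserverParams,
    pop: PopulationSpec,
    rng: np.random.Generator,
) -> dict:
    """One 2IFC trial: compare percepts of the ball and the cloud.

    The cloud interval carries no self-motion, so its percept is unbiased
    with the same speed Weber fraction.  Exact percept ties are broken by a
    fair coin.
    """
    direction = profile.direction if isinstance(profile, SelfMotionProfile) else profile
    ball_perc = perceived_speed_sample(v_ball, direction, obs, pop.nominal_self_speed, rng)
    cloud_sd = obs.weber_speed * cloud_speed
    cloud_perc = (
        _truncated_normal(rng, cloud_speed, cloud_sd, PERCEPT_FLOOR) if cloud_sd > 0 else cloud_speed
    )
    if cloud_perc == ball_perc:
        chose = bool(rng.random() < 0.5)
    else:
        chose = bool(cloud_perc > ball_perc)
    return {
        "participant_id": obs.participant_id,
        "ball_speed_mps": v_ball,
        "motion_profile": direction,
        "cloud_speed_mps": cloud_speed,
        "chose_cloud": chose,
    }


@dataclass(frozen=True)
class SpeedDesign:
    """Layout of the 2IFC speed-estimation task: two PEST tracks (one
    starting 30% above, one 30% below the ball speed) per speed x profile."""

    n_participants: int = 40
    speeds: Sequence[float] = BALL_SPEEDS
    profiles: Sequence[str] = PROFILES
    start_offsets: Sequence[float] = pest.START_OFFSETS
    min_trials: int = 30
    max_trials: int = 37

    def staircase_grid(self) -> pd.DataFrame:
        rows = [
            (v, p, o)
            for v in self.speeds
            for p in self.profiles
            for o in self.start_offsets
        ]
        return pd.DataFrame(rows, columns=["ball_speed_mps", "motion_profile", "start_offset"])

    @property
    def staircases_per_participant(self) -> int:
        return len(self.speeds) * len(self.profiles) * len(self.start_offsets)


def make_observer_responder(
    meta: pd.DataFrame,
    observers: Sequence[ObserverParams],
    pop: PopulationSpec,
    rng: np.random.Generator,
    z_ball: np.ndarray | None = None,
    z_cloud: np.ndarray | None = None,
):
    """Vectorised 2IFC responder over a staircase metadata table.

    ``meta`` needs columns ``participant_id``, ``ball_speed_mps``,
    ``motion_profile`` (row order = track order).  Optional pre-drawn
    standard-normal matrices ``z_ball``/``z_cloud`` of shape
    ``(n_tracks, max_trials)`` make the responder deterministic given the
    track and trial index -- the common-random-numbers hook used by the
    simulation-based fitting.
    """
    obs_by_id = {o.participant_id: o for o in observers}
    mean = np.empty(len(meta))
    sd_ball = np.empty(len(meta))
    weber = np.empty(len(meta))
    for i, row in enumerate(meta.itertuples(index=False)):
        o = obs_by_id[row.participant_id]
        m, s = perceived_speed_mean_sd(
            row.ball_speed_mps, row.motion_profile, o, pop.nominal_self_speed
        )
        mean[i], sd_ball[i], weber[i] = m, s, o.weber_speed

    def responder(levels: np.ndarray, idx: np.ndarray, trial: int) -> np.ndarray:
        if z_ball is None:
            zb = rng.standard_normal(idx.size)
            zc = rng.standard_normal(idx.size)
        else:
            zb = z_ball[idx, trial - 1]
            zc = z_cloud[idx, trial - 1]
        ball = np.maximum(mean[idx] + sd_ball[idx] * zb, PERCEPT_FLOOR)
        cloud = np.maximum(levels + weber[idx] * levels * zc, PERCEPT_FLOOR)
        return cloud > ball

    return responder


def simulate_speed_experiment(
    design: SpeedDesign,
    pop: PopulationSpec,
    rng: np.random.Generator | int | None = None,
    observers: Sequence[ObserverParams] | None = None,
) -> pd.DataFrame:
    """Simulate all PEST tracks of the speed-estimation task for a cohort.

    Returns the trial table (``participant_id``, ``staircase_id``,
    ``trial_index``, ``ball_speed_mps``, ``motion_profile``,
    ``start_offset``, ``cloud_speed_mps``, ``chose_cloud``).
    """
    rng = np.random.default_rng(rng)
    if observers is None:
        observers = _draw_observers(pop, design.n_participants, rng)
    grid = design.staircase_grid()
    meta = pd.concat(
        [grid.assign(participant_id=o.participant_id) for o in observers],
        ignore_index=True,
    )
    configs = [
        pest.StaircaseConfig(
            reference_speed=row.ball_speed_mps,
            start_offset=row.start_offset,
            min_trials=design.min_trials,
            max_trials=design.max_trials,
        )
        for row in meta.itertuples(index=False)
    ]
    responder = make_observer_responder(meta, observers, pop, rng)
    levels, responses, n_trials = pest.run_staircases_batch(configs, responder)

    n_tracks, width = levels.shape
    valid = np.arange(width)[None, :] < n_trials[:, None]
    track, trial = np.nonzero(valid)
    return pd.DataFrame(
        {
            "participant_id": meta["participant_id"].to_numpy()[track],
            "staircase_id": track,
            "trial_index": trial + 1,
            "ball_speed_mps": meta["ball_speed_mps"].to_numpy()[track],
            "motion_profile": meta["motion_profile"].to_numpy()[track],
            "start_offset": meta["start_offset"].to_numpy()[track],
            "cloud_speed_mps": levels[valid],
            "chose_cloud": responses[valid],
        }
    )
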