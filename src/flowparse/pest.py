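"""Modified PEST adaptive staircase for the 2IFC speed-estimation task.

The comparison stimulus (a ball cloud) follows Parameter Estimation by
Sequential Testing with the classic Taylor-Creelman step-size heuristics,
targeting the 50% point of "cloud judged faster" (the PSE):

* a response "cloud faster" moves the cloud speed down, otherwise up;
* every reversal halves the step;
* the second successive step in one direction keeps its size; the third and
  later ones double it -- except that the third step is not doubled when the
  run preceding the last reversal ended with a doubling (then the fourth
  doubles);
* the adapted step is capped at the maximum step (the early-phase step).

Modifications to the classic recipe, matching the task design: the applied
step is fixed at twice the initial step (1.2 m/s) for the first ten trials
to spread the sampled levels; levels are clipped to [reference/3,
3*reference]; a track stops after 37 trials, or once at least 30 trials are
done and the adapted step has fallen below 0.03 m/s.  Each response moves
the track (no Wald run criterion); the rule set lives in one function so a
different variant can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "init_staircase",
    "update",
    "run_staircase",
    "run_staircases_batch",
    "START_OFFSETS",
]

START_OFFSETS = (0.30, -0.30)


@dataclass(frozen=True)
class StaircaseConfig:
    reference_speed: float
    start_offset: float
    initial_step: float = 0.6
    early_step: float | None = None  # defaults to 2 * initial_step
    early_trial_count: int = 10
    min_trials: int = 30
    max_trials: int = 37
    stop_step: float = 0.03

    def __post_init__(self) -> None:
        if self.reference_speed <= 0:
            raise ValueError("reference_speed must be positive")
        if self.min_trials > self.max_trials:
            raise ValueError("min_trials must not exceed max_trials")
        if self.stop_step >= self.initial_step:
            raise ValueError("stop_step must be smaller than initial_step")
        if self.early_step is None:
            object.__setattr__(self, "early_step", 2 * self.initial_step)

    @property
    def lower_bound(self) -> float:
        return self.reference_speed / 3.0

    @property
    def upper_bound(self) -> float:
        return 3.0 * self.reference_speed

    @property
    def start_level(self) -> float:
        return self.reference_speed * (1.0 + self.start_offset)


@dataclass
class StaircaseState:
    config: StaircaseConfig
    current_level: float
    current_step: float  # the step that will be applied to the next response
    n_trials: int = 0
    last_direction: int = 0  # +1 up, -1 down, 0 none yet
    steps_same_direction: int = 0
    doubled_on_last_run: bool = False
    doubled_before_last_reversal: bool = False
    terminated: bool = False
    history: list = field(default_factory=list)  # (level, response) pairs
    applied_steps: list = field(default_factory=list)  # step used after each response
    _adapted_step: float = 0.0  # rule-driven step, overridden early on

    @property
    def levels(self) -> np.ndarray:
        return np.array([h[0] for h in self.history])

    @property
    def responses(self) -> np.ndarray:
        return np.array([h[1] for h in self.history], dtype=bool)


def init_staircase(config: StaircaseConfig) -> StaircaseState:
    """Fresh staircase at reference * (1 + start_offset)."""
    level = config.start_level
    if not (config.lower_bound <= level <= config.upper_bound):
        raise ValueError(
            f"start level {level:.3g} outside bounds "
            f"[{config.lower_bound:.3g}, {config.upper_bound:.3g}]"
        )
    return StaircaseState(
        config=config,
        current_level=level,
        current_step=config.early_step,
        _adapted_step=config.initial_step,
    )


def _apply_rules(state: StaircaseState, direction: int) -> float:
    """Taylor-Creelman step bookkeeping; returns the adapted step.

    Mutates the run-tracking fields of ``state``.  Called only after the
    early fixed-step phase; during that phase only the run direction is
    tracked, so the adapted step enters trial 11 still at its initial value.
    """
    cfg = state.config
    if state.last_direction != 0 and direction != state.last_direction:
        # reversal: halve, remember whether the finished run had doubled
        state._adapted_step /= 2.0
        state.doubled_before_last_reversal = state.doubled_on_last_run
        state.doubled_on_last_run = False
        state.steps_same_direction = 1
    else:
        state.steps_same_direction += 1
        n_same = state.steps_same_direction
        if n_same >= 4 or (n_same == 3 and not state.doubled_before_last_reversal):
            state._adapted_step = min(2.0 * state._adapted_step, cfg.early_step)
            state.doubled_on_last_run = True
    state.last_direction = direction
    return state._adapted_step


def update(state: StaircaseState, response: bool) -> StaircaseState:
    """Record one response at the current level and advance the track.

    ``response`` is ``chose_cloud_faster``; True steps the cloud speed down
    (toward the 50% point from above), False steps it up.
    """
    if state.terminated:
        raise RuntimeError("cannot update a terminated staircase")
    cfg = state.config
    state.history.append((state.current_level, bool(response)))
    state.n_trials += 1
    direction = -1 if response else 1

    if state.n_trials <= cfg.early_trial_count:
        # fixed wide step; track the run direction but leave the step alone
        if state.last_direction == 0 or direction == state.last_direction:
            state.steps_same_direction += 1
        else:
            state.steps_same_direction = 1
        state.last_direction = direction
        applied = cfg.early_step
    else:
        applied = _apply_rules(state, direction)

    state.applied_steps.append(applied)
    state.current_level = float(
        np.clip(state.current_level + direction * applied, cfg.lower_bound, cfg.upper_bound)
    )
    state.current_step = (
        cfg.early_step if state.n_trials < cfg.early_trial_count else state._adapted_step
    )
    if state.n_trials >= cfg.max_trials:
        state.terminated = True
    elif state.n_trials >= cfg.min_trials and state._adapted_step < cfg.stop_step:
        state.terminated = True
    return state


def run_staircase(
    config: StaircaseConfig,
    responder: Callable[[float], bool],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, StaircaseState]:
    """Drive one staircase to termination with a response callable.

    ``responder(level) -> bool`` answers whether the comparison at ``level``
    was judged faster; it may itself consume ``rng``.  Returns the trial
    history (``trial_index``, ``cloud_speed_mps``, ``chose_cloud``) and the
    final state.
    """
    state = init_staircase(config)
    while not state.terminated:
        try:
            response = responder(state.current_level)
        except Exception as exc:  # pragma: no cover - plumbing
            raise RuntimeError(
                f"responder failed at level {state.current_level:.3f} "
                f"(trial {state.n_trials + 1})"
            ) from exc
        update(state, response)
    hist = pd.DataFrame(
        {
            "trial_index": np.arange(1, state.n_trials + 1),
            "cloud_speed_mps": state.levels,
            "chose_cloud": state.responses,
        }
    )
    return hist, state


def run_staircases_batch(
    configs: Sequence[StaircaseConfig],
    responder: Callable[[np.ndarray, np.ndarray, int], np.ndarray],
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance many staircases in lockstep (vectorised over tracks).

    ``responder(levels, track_indices, trial_number)`` returns a boolean
    array of "cloud faster" responses for the active tracks.  Returns
    ``(levels, responses, n_trials)`` where the first two are
    ``(n_tracks, max_trials)`` arrays padded with NaN / False beyond each
    track's termination point.

    Equivalent, track for track, to repeated :func:`update`; kept separate
    so whole-cohort simulations stay cheap.
    """
    S = len(configs)
    cfg0 = configs[0]
    for c in configs:
        if (
            c.initial_step != cfg0.initial_step
            or c.early_step != cfg0.early_step
            or c.early_trial_count != cfg0.early_trial_count
            or c.min_trials != cfg0.min_trials
            or c.max_trials != cfg0.max_trials
            or c.stop_step != cfg0.stop_step
        ):
            raise ValueError("batch staircases must share step/termination settings")
    lower = np.array([c.lower_bound for c in configs])
    upper = np.array([c.upper_bound for c in configs])
    level = np.array([c.start_level for c in configs], dtype=float)
    if np.any(level < lower) or np.any(level > upper):
        raise ValueError("start level outside bounds")
    adapted = np.full(S, cfg0.initial_step)
    last_dir = np.zeros(S, dtype=int)
    same_count = np.zeros(S, dtype=int)
    run_double = np.zeros(S, dtype=bool)
    prev_run_double = np.zeros(S, dtype=bool)
    terminated = np.zeros(S, dtype=bool)
    n_trials = np.zeros(S, dtype=int)

    levels_out = np.full((S, cfg0.max_trials), np.nan)
    resp_out = np.zeros((S, cfg0.max_trials), dtype=bool)

    for t in range(cfg0.max_trials):
        active = ~terminated
        if not active.any():
            break
        idx = np.flatnonzero(active)
        resp = np.asarray(responder(level[idx], idx, t + 1), dtype=bool)
        levels_out[idx, t] = level[idx]
        resp_out[idx, t] = resp
        n_trials[idx] += 1
        direction = np.where(resp, -1, 1)

        early = (t + 1) <= cfg0.early_trial_count
        if early:
            cont = (last_dir[idx] == 0) | (direction == last_dir[idx])
            same_count[idx] = np.where(cont, same_count[idx] + 1, 1)
            applied = np.full(idx.size, cfg0.early_step)
        else:
            rev = (last_dir[idx] != 0) & (direction != last_dir[idx])
            r = idx[rev]
            adapted[r] /= 2.0
            prev_run_double[r] = run_double[r]
            run_double[r] = False
            same_count[r] = 1
            s = idx[~rev]
            same_count[s] += 1
            dbl = s[
                (same_count[s] >= 4)
                | ((same_count[s] == 3) & ~prev_run_double[s])
            ]
            adapted[dbl] = np.minimum(2.0 * adapted[dbl], cfg0.early_step)
            run_double[dbl] = True
            applied = adapted[idx]
        last_dir[idx] = direction
        level[idx] = np.clip(level[idx] + direction * applied, lower[idx], upper[idx])

        if t + 1 >= cfg0.max_trials:
            terminated[idx] = True
        elif t + 1 >= cfg0.min_trials:
            terminated[idx] |= adapted[idx] < cfg0.stop_step
    return levels_out, resp_out, n_trials
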