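"""Monte Carlo power and false-positive-rate estimation.

Power for the hierarchical design cannot be derived analytically, so it is
estimated by simulation: draw a cohort from the population model, simulate
both tasks, run the confirmatory battery, record rejections at alpha, and
repeat.  Rejection proportions come with exact (Clopper-Pearson) binomial
intervals.  With all generative effects at zero the same machinery
estimates the false-positive rate, which should sit near alpha.

Significance inside these loops uses the fast path of the pipeline
(asymptotic Wald tests for fixed effects, LRTs for the model comparisons);
the bootstrap path is reserved for one-off confirmatory analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import stats as fp_stats
from .kinematics import BALL_SPEEDS, MAIN_OCCLUSIONS, PROFILES
from .observer import (
    PopulationSpec,
    PredictionDesign,
    SpeedDesign,
    _draw_observers,
    simulate_prediction_experiment,
    simulate_speed_experiment,
)
from .psychometrics import fit_all

__all__ = ["DesignSpec", "PowerResult", "run_power", "ALL_TESTS"]

log = logging.getLogger("flowparse.power")

ALL_TESTS = ("h1a", "h1b", "h2a", "h2b", "h3a", "h3b")
_PREDICTION_TESTS = {"h1a", "h1b"}
_SPEED_TESTS = {"h2a", "h2b", "h3a", "h3b"}


@dataclass(frozen=True)
class DesignSpec:
    """One cell of the design grid explored by the power analysis."""

    n_participants: int = 40
    prediction_repetitions: int = 13
    staircase_min_trials: int = 30
    staircase_max_trials: int = 37
    speeds: Sequence[float] = BALL_SPEEDS
    occlusions: Sequence[float] = MAIN_OCCLUSIONS
    profiles: Sequence[str] = PROFILES
    alpha: float = 0.05
    n_simulations: int = 250

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be positive")

    @property
    def trials_per_speed_condition(self) -> tuple[int, int]:
        """Pooled 2IFC trials per speed x profile cell (two staircases)."""
        return 2 * self.staircase_min_trials, 2 * self.staircase_max_trials


@dataclass(frozen=True)
class PowerResult:
    """Rejection proportions with exact binomial 95% intervals."""

    rates: dict  # test -> {"rate", "ci_low", "ci_high", "n"}
    n_simulations: int
    n_failures: int
    alpha: float
    design: dict = field(default_factory=dict)

    def rate(self, test: str) -> float:
        return self.rates[test]["rate"]


def _binomial_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson interval for a proportion."""
    lo_q = (1 - level) / 2
    lo = 0.0 if k == 0 else float(sps.beta.ppf(lo_q, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - lo_q, k + 1, n - k))
    return lo, hi


def _one_simulation(design: DesignSpec, pop: PopulationSpec, tests, rng, direction):
    pred_design = PredictionDesign(
        n_participants=design.n_participants,
        repetitions=design.prediction_repetitions,
        speeds=design.speeds,
        profiles=design.profiles,
        occlusions=design.occlusions,
        include_static_extra=False,
    )
    observers = _draw_observers(pop, design.n_participants, rng)
    rejections = {}
    need_speed = bool(set(tests) & _SPEED_TESTS)
    kept_sum = None
    if set(tests) & _PREDICTION_TESTS or "h3a" in tests or "h3b" in tests:
        pred = simulate_prediction_experiment(pred_design, pop, rng, observers=observers)
        kept, _ = fp_stats.filter_prediction_trials(pred)
        if "h1a" in tests:
            lmm = fp_stats.accuracy_lmm_prediction(kept)
            rejections["h1a"] = lmm.pvalue("T." + direction) < design.alpha
        summaries = fp_stats.condition_summaries(kept, occlusions=tuple(design.occlusions))
        kept_sum, _ = fp_stats.filter_low_sd(summaries)
        if "h1b" in tests:
            lrt = fp_stats.precision_lrt_prediction(kept_sum, direction)
            rejections["h1b"] = lrt.p_value < design.alpha
    if need_speed:
        speed_design = SpeedDesign(
            n_participants=design.n_participants,
            speeds=design.speeds,
            profiles=design.profiles,
            min_trials=design.staircase_min_trials,
            max_trials=design.staircase_max_trials,
        )
        speed = simulate_speed_experiment(speed_design, pop, rng, observers=observers)
        kept_stair, _ = fp_stats.filter_staircases(speed)
        fits = fit_all(kept_stair)
        if "h2a" in tests:
            lmm = fp_stats.pse_lmm(fits)
            rejections["h2a"] = lmm.pvalue("T." + direction) < design.alpha
        if "h2b" in tests:
            lrt = fp_stats.jnd_lrt(fits, direction)
            rejections["h2b"] = lrt.p_value < design.alpha
        if "h3a" in tests or "h3b" in tests:
            diffs = fp_stats.participant_differences(kept_sum, fits, direction)
            if "h3a" in tests:
                slope = fp_stats.bias_correlation(diffs)
                rejections["h3a"] = slope.p_value < design.alpha
            if "h3b" in tests:
                lrt = fp_stats.precision_link_lrt(diffs)
                rejections["h3b"] = lrt.p_value < design.alpha
    return rejections


def run_power(
    design: DesignSpec,
    pop: PopulationSpec,
    tests: Sequence[str] = ALL_TESTS,
    seed: int | np.random.SeedSequence | None = None,
    direction: str = "opposite",
    n_simulations: int | None = None,
) -> PowerResult:
    """Monte Carlo rejection rates of the confirmatory tests.

    Each simulation draws a fresh cohort and dataset pair, runs the
    requested tests at ``design.alpha``, and records which rejected.  A
    simulation that errors out (e.g. a degenerate fit) is logged and
    excluded; the failure count is part of the result.  Fully reproducible
    under a fixed seed.
    """
    unknown = set(tests) - set(ALL_TESTS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    n_sims = design.n_simulations if n_simulations is None else int(n_simulations)
    if n_sims < 1:
        raise ValueError("n_simulations must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    counters = {t: 0 for t in tests}
    successes = {t: 0 for t in tests}
    failures = 0
    for i, child in enumerate(ss.spawn(n_sims)):
        rng = np.random.default_rng(child)
        try:
            rejections = _one_simulation(design, pop, tests, rng, direction)
        except Exception as exc:
            failures += 1
            log.warning("simulation %d failed: %s", i, exc)
            continue
        for t in tests:
            if t in rejections:
                successes[t] += 1
                counters[t] += bool(rejections[t])
    rates = {}
    for t in tests:
        n = successes[t]
        k = counters[t]
        lo, hi = _binomial_interval(k, n) if n else (0.0, 1.0)
        rates[t] = {"rate": k / n if n else float("nan"), "ci_low": lo, "ci_high": hi, "n": n}
    return PowerResult(
        rates=rates,
        n_simulations=n_sims,
        n_failures=failures,
        alpha=design.alpha,
        design=asdict(design),
    )
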