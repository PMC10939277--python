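"""Two-step simulation-based estimation of per-participant self-motion effects.

For each participant, task (prediction vs speed estimation) and self-motion
direction (same vs opposite), two scalar parameters are estimated against
the generative observer model:

* an accuracy parameter -- the fraction of the nominal self-motion speed
  wrongly attributed to the ball (bounded to [-1, 1]);
* a precision parameter -- the fractional inflation of perceived-speed
  variability under self-motion (searched over (-0.9, 3]).

Fitting is in two steps: with the precision parameter pinned at zero, the
accuracy parameter is found by bounded scalar minimisation (Brent-style) of
the root median squared error between observed and simulated
condition-level differences (self-motion minus static); then, with the
accuracy parameter fixed, the precision parameter is fitted the same way on
the variability summaries.  For the prediction task the summaries are mean
timing errors and their SDs per speed x occlusion cell; for the speed task
they are PSEs and JNDs per ball speed.

Because the objective is a Monte Carlo quantity, each optimisation reuses
one set of pre-drawn random numbers across candidate parameter values
(common random numbers): the objective becomes a smooth deterministic
function of the parameter, which is what makes a bracketing scalar search
well-posed.  The simulated datasets use the population-mean Weber fractions
-- a participant's true internal noise is not observable, and the accuracy
objective is insensitive to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import minimize_scalar

from . import pest
from .kinematics import BALL_SPEEDS, MAIN_OCCLUSIONS
from .observer import PERCEPT_FLOOR, PopulationSpec
from .psychometrics import fit_cumulative_gaussian_batch

__all__ = [
    "FittedEffect",
    "summarize_prediction_differences",
    "summarize_speed_differences",
    "PredictionTaskSimulator",
    "SpeedTaskSimulator",
    "fit_accuracy_param",
    "fit_precision_param",
    "fit_participant_prediction",
    "fit_participant_speed",
    "fit_cohort",
    "cross_task_regression",
    "one_sample_tests",
]

ACCURACY_BOUNDS = (-1.0, 1.0)
PRECISION_BOUNDS = (-0.9, 3.0)
_XATOL = 1e-3


@dataclass(frozen=True)
class FittedEffect:
    participant_id: int
    task: str  # "prediction" | "speed_estimation"
    direction: str  # "same" | "opposite"
    accuracy_param: float
    precision_param: float
    objective_accuracy: float
    objective_precision: float
    n_sim_datasets: int


def _rmedse(sim: np.ndarray, obs: np.ndarray) -> float:
    """Median over datasets of sqrt(median over cells of squared error)."""
    err = (sim - obs[None, :]) ** 2
    return float(np.median(np.sqrt(np.median(err, axis=1))))


# ---------------------------------------------------------------------------
# observed summaries


def summarize_prediction_differences(
    trials: pd.DataFrame,
    direction: str,
    occlusions: Sequence[float] = MAIN_OCCLUSIONS,
) -> pd.DataFrame:
    """Per (speed, occlusion) mean-error and SD differences vs static for
    one participant's prediction data."""
    sub = trials[
        trials["motion_profile"].isin(["static", direction])
        & trials["occlusion_s"].isin(occlusions)
    ]
    g = (
        sub.groupby(["ball_speed_mps", "occlusion_s", "motion_profile"])["error_s"]
        .agg(["mean", "std"])
        .unstack("motion_profile")
    )
    try:
        d_mean = g[("mean", direction)] - g[("mean", "static")]
        d_sd = g[("std", direction)] - g[("std", "static")]
    except KeyError as exc:
        raise ValueError(f"missing condition cells: {exc}") from exc
    out = pd.DataFrame({"d_mean": d_mean, "d_sd": d_sd}).reset_index()
    if out[["d_mean", "d_sd"]].isna().any().any():
        raise ValueError("incomplete condition cells for difference summary")
    return out


def summarize_speed_differences(fits: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Per-speed PSE and JND differences vs static for one participant."""
    sub = fits[fits["motion_profile"].isin(["static", direction])]
    g = sub.set_index(["ball_speed_mps", "motion_profile"])[["pse_mps", "jnd_mps"]].unstack(
        "motion_profile"
    )
    try:
        d_pse = g[("pse_mps", direction)] - g[("pse_mps", "static")]
        d_jnd = g[("jnd_mps", direction)] - g[("jnd_mps", "static")]
    except KeyError as exc:
        raise ValueError(f"missing condition cells: {exc}") from exc
    out = pd.DataFrame({"d_pse": d_pse, "d_jnd": d_jnd}).reset_index()
    if out[["d_pse", "d_jnd"]].isna().any().any():
        raise ValueError("incomplete condition cells for difference summary")
    return out


# ---------------------------------------------------------------------------
# simulators with common random numbers


class PredictionTaskSimulator:
    """Simulates prediction-task difference summaries for candidate params.

    All noise is pre-drawn at construction, so repeated calls with
    different candidate values share the same random numbers.
    """

    def __init__(
        self,
        pop: PopulationSpec,
        rng: np.random.Generator,
        repetitions: int,
        n_sim: int = 50,
        speeds: Sequence[float] = BALL_SPEEDS,
        occlusions: Sequence[float] = MAIN_OCCLUSIONS,
    ):
        if n_sim < 25:
            raise ValueError("need at least 25 simulated datasets")
        self.pop = pop
        self.n_sim = n_sim
        cells = [(v, o) for v in speeds for o in occlusions]
        self.v = np.array([c[0] for c in cells])
        self.occ = np.array([c[1] for c in cells])
        shape = (n_sim, len(cells), repetitions)
        self._z = {
            key: rng.standard_normal(shape)
            for key in ("v_dir", "v_stat", "d_dir", "d_stat")
        }

    def _errors(self, accuracy: float, precision: float, which: str) -> np.ndarray:
        pop = self.pop
        v = self.v[None, :, None]
        occ = self.occ[None, :, None]
        mean = v + accuracy * pop.nominal_self_speed
        sd = pop.weber_speed_mean * mean * (1.0 + precision)
        v_perc = np.maximum(mean + sd * self._z["v_" + which], PERCEPT_FLOOR)
        d = occ * v
        d_perc = np.maximum(d * (1.0 + pop.weber_distance * self._z["d_" + which]), 0.01)
        return d_perc / v_perc - occ

    def diff_summaries(self, accuracy: float, precision: float):
        """(n_sim, n_cells) arrays of mean-error and SD differences."""
        err_dir = self._errors(accuracy, precision, "dir")
        err_stat = self._errors(0.0, 0.0, "stat")
        d_mean = err_dir.mean(axis=2) - err_stat.mean(axis=2)
        d_sd = err_dir.std(axis=2, ddof=1) - err_stat.std(axis=2, ddof=1)
        return d_mean, d_sd


class SpeedTaskSimulator:
    """Simulates speed-task PSE/JND difference summaries for candidate params.

    Each simulated dataset runs the full PEST tracks (two start offsets per
    speed for both the self-motion and the static profile) against the
    candidate observer, then fits psychometric functions per speed x
    profile.  The per-trial percept noise is pre-drawn (common random
    numbers), so the staircase paths respond smoothly to the parameter.
    """

    def __init__(
        self,
        pop: PopulationSpec,
        rng: np.random.Generator,
        n_sim: int = 25,
        speeds: Sequence[float] = BALL_SPEEDS,
        start_offsets: Sequence[float] = pest.START_OFFSETS,
        min_trials: int = 30,
        max_trials: int = 37,
    ):
        if n_sim < 25:
            raise ValueError("need at least 25 simulated datasets")
        self.pop = pop
        self.n_sim = n_sim
        self.speeds = tuple(speeds)
        # track layout: (sim, speed, profile in {dir, static}, offset)
        layout = [
            (s, v, prof, off)
            for s in range(n_sim)
            for v in self.speeds
            for prof in (1, 0)  # 1 = self-motion profile, 0 = static
            for off in start_offsets
        ]
        self.track_v = np.array([t[1] for t in layout])
        self.track_is_dir = np.array([t[2] for t in layout], dtype=bool)
        self.configs = [
            pest.StaircaseConfig(
                reference_speed=t[1],
                start_offset=t[3],
                min_trials=min_trials,
                max_trials=max_trials,
            )
            for t in layout
        ]
        n_tracks = len(layout)
        self._sim_idx = np.array([t[0] for t in layout])
        self._z_ball = rng.standard_normal((n_tracks, max_trials))
        self._z_cloud = rng.standard_normal((n_tracks, max_trials))

    def diff_summaries(self, accuracy: float, precision: float):
        """(n_sim, n_speeds) arrays of PSE and JND differences."""
        pop = self.pop
        mean = self.track_v + np.where(self.track_is_dir, accuracy, 0.0) * pop.nominal_self_speed
        sd = pop.weber_speed_mean * mean * np.where(self.track_is_dir, 1.0 + precision, 1.0)

        def responder(levels, idx, trial):
            zb = self._z_ball[idx, trial - 1]
            zc = self._z_cloud[idx, trial - 1]
            ball = np.maximum(mean[idx] + sd[idx] * zb, PERCEPT_FLOOR)
            cloud = np.maximum(levels * (1.0 + pop.weber_speed_mean * zc), PERCEPT_FLOOR)
            return cloud > ball

        levels, responses, n_trials = pest.run_staircases_batch(self.configs, responder)
        # pool the two offsets of each (sim, speed, profile) cell
        cells = []
        n_speeds = len(self.speeds)
        per_cell = 2  # offsets
        stride = n_speeds * 2 * per_cell
        for s in range(self.n_sim):
            for j in range(n_speeds):
                for prof in (1, 0):
                    base = s * stride + j * 2 * per_cell + (0 if prof == 1 else per_cell)
                    xs, ys = [], []
                    for k in (base, base + 1):
                        n = n_trials[k]
                        xs.append(levels[k, :n])
                        ys.append(responses[k, :n])
                    cells.append((np.concatenate(xs), np.concatenate(ys)))
        fitted = fit_cumulative_gaussian_batch(cells)
        fitted = fitted.reshape(self.n_sim, n_speeds, 2, 2)  # (sim, speed, profile, [pse, jnd])
        d = fitted[:, :, 0, :] - fitted[:, :, 1, :]  # dir minus static
        return d[..., 0], d[..., 1]


# ---------------------------------------------------------------------------
# scalar fits


def _fit_scalar(objective, bounds) -> tuple[float, float]:
    res = minimize_scalar(objective, bounds=bounds, method="bounded", options={"xatol": _XATOL})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite objective at {res.x}")
    return float(res.x), float(res.fun)


def fit_accuracy_param(observed: np.ndarray, simulator, bounds=ACCURACY_BOUNDS):
    """Step one: precision pinned at zero, accuracy free."""
    obs = np.asarray(observed, dtype=float)

    def objective(a):
        sim_mean, _ = simulator.diff_summaries(a, 0.0)
        return _rmedse(sim_mean, obs)

    return _fit_scalar(objective, bounds)


def fit_precision_param(observed: np.ndarray, simulator, accuracy: float, bounds=PRECISION_BOUNDS):
    """Step two: accuracy fixed at its fitted value, precision free."""
    obs = np.asarray(observed, dtype=float)

    def objective(p):
        _, sim_sd = simulator.diff_summaries(accuracy, p)
        return _rmedse(sim_sd, obs)

    return _fit_scalar(objective, bounds)


def fit_participant_prediction(
    trials: pd.DataFrame,
    pop: PopulationSpec,
    direction: str,
    rng: np.random.Generator,
    repetitions: int | None = None,
    n_sim: int = 50,
    fit_precision: bool = True,
) -> FittedEffect:
    """Two-step fit of one participant's prediction-task data."""
    summary = summarize_prediction_differences(trials, direction)
    if repetitions is None:
        counts = trials[trials["occlusion_s"].isin(MAIN_OCCLUSIONS)].groupby(
            ["ball_speed_mps", "occlusion_s", "motion_profile"]
        ).size()
        repetitions = int(round(counts.median()))
    sim = PredictionTaskSimulator(pop, rng, repetitions=repetitions, n_sim=n_sim)
    acc, obj_a = fit_accuracy_param(summary["d_mean"].to_numpy(), sim)
    if fit_precision:
        prec, obj_p = fit_precision_param(summary["d_sd"].to_numpy(), sim, acc)
    else:
        prec, obj_p = float("nan"), float("nan")
    pid = int(trials["participant_id"].iloc[0])
    return FittedEffect(pid, "prediction", direction, acc, prec, obj_a, obj_p, n_sim)


def fit_participant_speed(
    fits: pd.DataFrame,
    pop: PopulationSpec,
    direction: str,
    rng: np.random.Generator,
    n_sim: int = 25,
    fit_precision: bool = True,
    min_trials: int = 30,
    max_trials: int = 37,
) -> FittedEffect:
    """Two-step fit of one participant's psychometric summaries."""
    summary = summarize_speed_differences(fits, direction)
    sim = SpeedTaskSimulator(
        pop, rng, n_sim=n_sim, min_trials=min_trials, max_trials=max_trials
    )
    acc, obj_a = fit_accuracy_param(summary["d_pse"].to_numpy(), sim)
    if fit_precision:
        prec, obj_p = fit_precision_param(summary["d_jnd"].to_numpy(), sim, acc)
    else:
        prec, obj_p = float("nan"), float("nan")
    pid = int(fits["participant_id"].iloc[0])
    return FittedEffect(pid, "speed_estimation", direction, acc, prec, obj_a, obj_p, n_sim)


def fit_cohort(
    pred_trials: pd.DataFrame,
    speed_fits: pd.DataFrame,
    pop: PopulationSpec,
    directions: Sequence[str] = ("opposite", "same"),
    seed: int | np.random.SeedSequence | None = None,
    n_sim_prediction: int = 50,
    n_sim_speed: int = 25,
    fit_precision: bool = True,
) -> pd.DataFrame:
    """Fit every participant x task x direction; returns a tidy table."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    pids = sorted(set(pred_trials["participant_id"]) & set(speed_fits["participant_id"]))
    rows = []
    children = ss.spawn(len(pids))
    for pid, child in zip(pids, children):
        rng = np.random.default_rng(child)
        p_trials = pred_trials[pred_trials["participant_id"] == pid]
        p_fits = speed_fits[speed_fits["participant_id"] == pid]
        for direction in directions:
            rows.append(
                fit_participant_prediction(
                    p_trials, pop, direction, rng,
                    n_sim=n_sim_prediction, fit_precision=fit_precision,
                )
            )
            rows.append(
                fit_participant_speed(
                    p_fits, pop, direction, rng,
                    n_sim=n_sim_speed, fit_precision=fit_precision,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# cohort-level summaries of the fitted parameters


def cross_task_regression(effects: pd.DataFrame) -> pd.DataFrame:
    """OLS slope of prediction-task on speed-task parameters.

    One row per direction x domain (accuracy/precision) with the slope, its
    95% CI and p-value; a shared underlying effect predicts a slope near 1.
    """
    rows = []
    for direction in sorted(effects["direction"].unique()):
        sub = effects[effects["direction"] == direction]
        wide = sub.pivot(
            index="participant_id", columns="task",
            values=["accuracy_param", "precision_param"],
        )
        for domain in ("accuracy_param", "precision_param"):
            try:
                df = pd.DataFrame(
                    {
                        "pred": wide[(domain, "prediction")],
                        "speed": wide[(domain, "speed_estimation")],
                    }
                ).dropna()
            except KeyError:
                continue
            if len(df) < 5:
                continue
            if np.std(df["speed"].to_numpy()) == 0:
                raise ValueError(f"degenerate regressor for {direction}/{domain}")
            res = smf.ols("pred ~ speed", df).fit()
            ci = res.conf_int().loc["speed"]
            rows.append(
                {
                    "direction": direction,
                    "domain": domain.replace("_param", ""),
                    "slope": float(res.params["speed"]),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "p_value": float(res.pvalues["speed"]),
                    "n": int(res.nobs),
                }
            )
    return pd.DataFrame(rows)


def one_sample_tests(effects: pd.DataFrame) -> pd.DataFrame:
    """Intercept-only regression (one-sample t-test) per task x direction x
    domain: is the cohort-mean effect different from zero?

    Degenerate (zero-variance) parameter sets get a NaN p-value and a note
    instead of a spurious test.
    """
    rows = []
    for (task, direction), sub in effects.groupby(["task", "direction"]):
        for domain in ("accuracy_param", "precision_param"):
            x = sub[domain].dropna().to_numpy()
            if x.size < 5:
                continue
            row = {
                "task": task,
                "direction": direction,
                "domain": domain.replace("_param", ""),
                "mean": float(x.mean()),
                "n": int(x.size),
                "note": "",
            }
            if np.std(x) == 0:
                row["p_value"] = float("nan")
                row["note"] = "zero variance: test refused"
            else:
                res = smf.ols("y ~ 1", pd.DataFrame({"y": x})).fit()
                row["p_value"] = float(res.pvalues["Intercept"])
            rows.append(row)
    return pd.DataFrame(rows)
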