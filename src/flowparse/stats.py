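"""Confirmatory statistical pipeline: exclusions, mixed models, LRTs.

The analyses mirror the study's confirmatory plan:

* accuracy in the prediction task -- a linear mixed model of the timing
  error on motion profile (static as reference) with a by-participant
  random slope for ball speed;
* precision in the prediction task -- a likelihood-ratio test of the motion
  profile on log condition SDs, controlling the condition mean;
* accuracy and precision in the speed task -- the same pair of analyses on
  PSEs and log JNDs from the psychometric fits;
* cross-task links -- per-participant opposite-minus-static differences
  regressed across tasks (a linear model for the means, a likelihood-ratio
  test for the variabilities).

Occlusion duration enters the trial-level models as a fixed factor: the
mixed-model backend has no crossed random effects, and with three to ten
occlusion levels a fixed factor is the transparent substitute (the formula
tag on every result records this).  All model pairs compared by LRT are fit
by full maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "LmmResult",
    "LrtResult",
    "SlopeResult",
    "filter_prediction_trials",
    "filter_staircases",
    "filter_low_sd",
    "condition_summaries",
    "accuracy_lmm_prediction",
    "precision_lrt_prediction",
    "pse_lmm",
    "jnd_lrt",
    "participant_differences",
    "bias_correlation",
    "precision_link_lrt",
    "bootstrap_fixed_effect_ci",
    "run_confirmatory",
    "SD_EXCLUSION_THRESHOLD",
]

SD_EXCLUSION_THRESHOLD = 0.01  # s; conditions this quiet are excluded from precision fits
_PROFILE_TERM = "C(motion_profile, Treatment('static'))"


@dataclass
class LmmResult:
    """Fixed-effect estimates from one linear mixed model."""

    formula_tag: str
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    llf: float
    converged: bool
    singular: bool
    n_obs: int
    result: object = field(repr=False, default=None)

    def coef(self, term_contains: str) -> float:
        name = self._match(term_contains)
        return float(self.params[name])

    def pvalue(self, term_contains: str) -> float:
        return float(self.pvalues[self._match(term_contains)])

    def ci(self, term_contains: str) -> tuple[float, float]:
        row = self.conf_int.loc[self._match(term_contains)]
        return float(row.iloc[0]), float(row.iloc[1])

    def _match(self, fragment: str) -> str:
        hits = [n for n in self.params.index if fragment in n]
        if len(hits) != 1:
            raise KeyError(f"{fragment!r} matches {hits} in {list(self.params.index)}")
        return hits[0]


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test between nested ML fits."""

    statistic: float
    df: int
    p_value: float
    llf_test: float
    llf_null: float
    coefficient: float = float("nan")  # profile/JND term in the test model (not interpreted)


@dataclass(frozen=True)
class SlopeResult:
    """A single regression slope with its 95% CI."""

    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    intercept: float
    n: int


# ---------------------------------------------------------------------------
# exclusion rules


def filter_prediction_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose response exceeds three times the occlusion duration.

    The cut is strict (">"), so a response at exactly 3x is kept.  Rows with
    non-finite responses are also collected into the dropped report.
    """
    bad_value = ~np.isfinite(trials["response_s"]) | (trials["response_s"] <= 0)
    too_late = trials["response_s"] > 3.0 * trials["occlusion_s"]
    dropped = trials[bad_value | too_late].copy()
    dropped["drop_reason"] = np.where(
        bad_value[bad_value | too_late], "malformed response", "response > 3x occlusion"
    )
    return trials[~(bad_value | too_late)].copy(), dropped


def filter_staircases(trials: pd.DataFrame, max_fraction_at_bounds: float = 0.20):
    """Drop staircases with too many levels pinned at the track bounds.

    A level counts as "at the limits" when it equals the staircase's lower
    bound (reference/3) or upper bound (3x reference); levels are clipped
    during the run, so contact is exact up to floating-point tolerance.
    """
    v = trials["ball_speed_mps"].to_numpy()
    lvl = trials["cloud_speed_mps"].to_numpy()
    at_bound = np.isclose(lvl, v / 3.0) | np.isclose(lvl, 3.0 * v)
    frac = (
        pd.Series(at_bound, index=trials.index)
        .groupby(trials["staircase_id"])
        .mean()
    )
    bad_ids = frac[frac > max_fraction_at_bounds].index
    keep = ~trials["staircase_id"].isin(bad_ids)
    return trials[keep].copy(), trials[~keep].copy()


def filter_low_sd(summaries: pd.DataFrame, threshold: float = SD_EXCLUSION_THRESHOLD):
    """Exclude condition summaries with SD at or below the threshold.

    Taking logs of near-zero SDs would let a handful of degenerate cells
    dominate the precision models.
    """
    keep = summaries["sd_extrapolated"] > threshold
    return summaries[keep].copy(), summaries[~keep].copy()


def condition_summaries(
    trials: pd.DataFrame, occlusions: tuple | None = None
) -> pd.DataFrame:
    """Per participant x speed x profile x occlusion mean/SD of the
    extrapolated (button-press) time."""
    df = trials
    if occlusions is not None:
        df = df[df["occlusion_s"].isin(occlusions)]
    g = df.groupby(
        ["participant_id", "ball_speed_mps", "motion_profile", "occlusion_s"], sort=True
    )["response_s"]
    out = g.agg(mean_extrapolated="mean", sd_extrapolated="std", n_trials="size").reset_index()
    out["mean_error"] = out["mean_extrapolated"] - out["occlusion_s"]
    return out


# ---------------------------------------------------------------------------
# mixed-model machinery

_FIT_METHODS = ("lbfgs", "bfgs", "cg")


def _fit_mixedlm(formula, data, re_formula="~ball_speed_mps", reml=False, thorough=False):
    """Fit a MixedLM with optimizer fallbacks; warnings are captured.

    With ``thorough=True`` every optimizer is run and the fit with the
    highest log-likelihood wins.  The LRT model pairs use this: a locally
    under-converged null fit would otherwise inflate the statistic.
    """
    model = smf.mixedlm(formula, data, groups=data["participant_id"], re_formula=re_formula)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _FIT_METHODS:
            try:
                res = model.fit(reml=reml, method=method, maxiter=200)
            except Exception:
                continue
            if not np.isfinite(res.llf):
                continue
            if best is None:
                best = res
            elif thorough:
                if res.llf > best.llf + 1e-10 or (
                    res.converged and not best.converged and res.llf >= best.llf - 1e-8
                ):
                    best = res
            elif res.converged and not best.converged:
                best = res
            if not thorough and best.converged:
                break
    if best is None:
        raise RuntimeError(f"mixed model failed to fit: {formula}")
    return best


def _is_singular(res) -> bool:
    try:
        ev = np.linalg.eigvalsh(np.asarray(res.cov_re, dtype=float))
        return bool(ev.min() < 1e-8 * max(ev.max(), 1.0))
    except Exception:
        return True


def _lmm_result(res, tag: str) -> LmmResult:
    fe = res.fe_params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = res.conf_int().loc[fe.index]
        pv = res.pvalues.loc[fe.index]
    return LmmResult(
        formula_tag=tag,
        params=fe,
        conf_int=ci,
        pvalues=pv,
        llf=float(res.llf),
        converged=bool(res.converged),
        singular=_is_singular(res),
        n_obs=int(res.nobs),
        result=res,
    )


def accuracy_lmm_prediction(trials: pd.DataFrame) -> LmmResult:
    """Timing error ~ motion profile, random ball-speed slope by participant,
    occlusion duration as a fixed factor (crossed random intercepts are not
    supported by the backend)."""
    formula = f"error_s ~ {_PROFILE_TERM} + C(occlusion_s)"
    res = _fit_mixedlm(formula, trials)
    return _lmm_result(
        res, "error ~ profile + occlusion[fixed] + (ball_speed | participant)"
    )


def _lrt(res_test, res_null, df: int, coefficient=float("nan")) -> LrtResult:
    stat = max(0.0, 2.0 * (float(res_test.llf) - float(res_null.llf)))
    return LrtResult(
        statistic=stat,
        df=df,
        p_value=float(sps.chi2.sf(stat, df)),
        llf_test=float(res_test.llf),
        llf_null=float(res_null.llf),
        coefficient=float(coefficient),
    )


def precision_lrt_prediction(summaries: pd.DataFrame, direction: str = "opposite") -> LrtResult:
    """LRT for a motion-profile effect on log condition SDs (one direction
    vs static), controlling the condition mean; both models by full ML."""
    sub = summaries[summaries["motion_profile"].isin(["static", direction])].copy()
    if (sub["sd_extrapolated"] <= 0).any():
        raise ValueError("apply filter_low_sd before the precision analysis")
    sub["log_sd"] = np.log(sub["sd_extrapolated"])
    if np.var(sub["log_sd"].to_numpy()) < 1e-16:
        # constant response: the profile term cannot explain anything
        return LrtResult(0.0, 1, 1.0, float("nan"), float("nan"), 0.0)
    test = _fit_mixedlm(
        f"log_sd ~ mean_extrapolated + {_PROFILE_TERM} + C(occlusion_s)", sub, thorough=True
    )
    null = _fit_mixedlm("log_sd ~ mean_extrapolated + C(occlusion_s)", sub, thorough=True)
    coef = test.fe_params[[i for i in test.fe_params.index if "T." + direction in i][0]]
    return _lrt(test, null, df=1, coefficient=coef)


def pse_lmm(fits: pd.DataFrame) -> LmmResult:
    """PSE ~ motion profile with a by-participant random ball-speed slope."""
    data = fits[fits["converged"]].rename(columns={"pse_mps": "pse"})
    res = _fit_mixedlm(f"pse ~ {_PROFILE_TERM}", data)
    return _lmm_result(res, "pse ~ profile + (ball_speed | participant)")


def jnd_lrt(fits: pd.DataFrame, direction: str = "opposite") -> LrtResult:
    """LRT for a profile effect on log JNDs (one direction vs static),
    controlling the PSE."""
    data = fits[fits["converged"]].copy()
    sub = data[data["motion_profile"].isin(["static", direction])].copy()
    sub["log_jnd"] = np.log(sub["jnd_mps"])
    sub["pse"] = sub["pse_mps"]
    if np.var(sub["log_jnd"].to_numpy()) < 1e-16:
        return LrtResult(0.0, 1, 1.0, float("nan"), float("nan"), 0.0)
    test = _fit_mixedlm(f"log_jnd ~ {_PROFILE_TERM} + pse", sub, thorough=True)
    null = _fit_mixedlm("log_jnd ~ pse", sub, thorough=True)
    coef = test.fe_params[[i for i in test.fe_params.index if "T." + direction in i][0]]
    return _lrt(test, null, df=1, coefficient=coef)


# ---------------------------------------------------------------------------
# cross-task analyses


def participant_differences(
    pred_summaries: pd.DataFrame, fits: pd.DataFrame, direction: str = "opposite"
) -> pd.DataFrame:
    """Per-participant (direction - static) differences for both tasks.

    Prediction task: difference of the participant's mean and SD of the
    extrapolated time (averaged over condition cells).  Speed task:
    difference of mean PSE and mean JND over ball speeds (converged fits
    only).  Participants missing either profile in either task are dropped.
    """
    def _task_diff(df, value_cols, profile_col="motion_profile"):
        wide = df.pivot_table(
            index="participant_id", columns=profile_col, values=value_cols, aggfunc="mean"
        )
        out = {}
        for col in value_cols:
            try:
                out[col] = wide[(col, direction)] - wide[(col, "static")]
            except KeyError as exc:
                raise ValueError(f"missing profile {exc} for {col}") from exc
        return pd.DataFrame(out)

    pred = _task_diff(pred_summaries, ["mean_extrapolated", "sd_extrapolated"])
    pred.columns = ["d_mean_extrap", "d_sd_extrap"]
    good = fits[fits["converged"]]
    speed = _task_diff(good, ["pse_mps", "jnd_mps"])
    speed.columns = ["d_pse", "d_jnd"]
    return pred.join(speed, how="inner").dropna().reset_index()


def _check_regressor(x: np.ndarray, name: str) -> None:
    if x.size < 5:
        raise ValueError("need at least 5 participants")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise ValueError(f"degenerate regressor {name}: no between-participant variation")


def bias_correlation(diffs: pd.DataFrame) -> SlopeResult:
    """Linear model: prediction-task mean difference on speed-task PSE
    difference; a negative slope links the two self-motion biases."""
    x = diffs["d_pse"].to_numpy()
    _check_regressor(x, "d_pse")
    res = smf.ols("d_mean_extrap ~ d_pse", diffs).fit()
    ci = res.conf_int().loc["d_pse"]
    return SlopeResult(
        slope=float(res.params["d_pse"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues["d_pse"]),
        intercept=float(res.params["Intercept"]),
        n=int(res.nobs),
    )


def precision_link_lrt(diffs: pd.DataFrame) -> LrtResult:
    """Nested-model test: does the speed-task JND difference explain
    variability in the prediction task beyond the mean difference?

    The models are ordinary linear regressions, so the comparison uses the
    exact partial F-test -- a monotone transform of the likelihood ratio
    that keeps its nominal size at small cohort sizes, where the asymptotic
    chi-square is anticonservative.
    """
    x = diffs["d_jnd"].to_numpy()
    _check_regressor(x, "d_jnd")
    test = smf.ols("d_sd_extrap ~ d_mean_extrap + d_jnd", diffs).fit()
    null = smf.ols("d_sd_extrap ~ d_mean_extrap", diffs).fit()
    f_stat, p_value, df_diff = test.compare_f_test(null)
    return LrtResult(
        statistic=float(f_stat),
        df=int(df_diff),
        p_value=float(p_value),
        llf_test=float(test.llf),
        llf_null=float(null.llf),
        coefficient=float(test.params["d_jnd"]),
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_fixed_effect_ci(
    lmm: LmmResult, n_boot: int = 500, seed: int | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Parametric-bootstrap percentile CIs for the fixed effects of a fit.

    Each replicate simulates responses from the fitted model (fixed effects
    + Gaussian random effects per participant + residual), refits, and
    collects the fixed-effect estimates.  Deterministic under a fixed seed.
    More than 10% failed refits triggers a warning but the interval is
    still formed from the successful replicates.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    res = lmm.result
    rng = np.random.default_rng(seed)
    model = res.model
    X = model.exog
    Z = model.exog_re
    groups = np.asarray(model.groups)
    beta = np.asarray(res.fe_params)
    cov_re = np.asarray(res.cov_re, dtype=float)  # already on the response scale
    scale = float(res.scale)
    chol = np.linalg.cholesky(cov_re + 1e-12 * np.eye(cov_re.shape[0]))
    labels = pd.unique(groups)
    draws = []
    failures = 0
    mean = X @ beta
    for _ in range(n_boot):
        u = {g: chol @ rng.standard_normal(chol.shape[0]) for g in labels}
        ranef = np.einsum("ij,ij->i", Z, np.stack([u[g] for g in groups]))
        y = mean + ranef + rng.normal(0.0, np.sqrt(scale), X.shape[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bres = sm.MixedLM(
                    y, X, groups=groups, exog_re=Z
                ).fit(reml=False, method="lbfgs", maxiter=200)
            draws.append(np.asarray(bres.fe_params))
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap refits failed; interval uses the rest",
            RuntimeWarning,
        )
    arr = np.array(draws)
    alpha = 1.0 - level
    lo = np.quantile(arr, alpha / 2, axis=0)
    hi = np.quantile(arr, 1 - alpha / 2, axis=0)
    return pd.DataFrame(
        {"ci_low": lo, "ci_high": hi}, index=lmm.params.index
    )


# ---------------------------------------------------------------------------
# one-call confirmatory battery


def run_confirmatory(
    pred_trials: pd.DataFrame,
    speed_trials: pd.DataFrame | None = None,
    fits: pd.DataFrame | None = None,
    direction: str = "opposite",
    alpha: float = 0.05,
    main_occlusions: tuple = (0.5, 0.6, 0.7),
) -> dict:
    """Run the six confirmatory tests on (possibly synthetic) trial tables.

    Fixed-effect significance uses asymptotic Wald p-values (the fast path
    appropriate for simulation loops); model comparisons use LRTs.  Either
    ``speed_trials`` (raw staircase records) or precomputed psychometric
    ``fits`` must be given for the speed-task and cross-task hypotheses.

    Returns a dict keyed h1a/h1b/h2a/h2b/h3a/h3b with the test statistic,
    p-value and rejection flag at ``alpha``.
    """
    from .psychometrics import fit_all

    out: dict[str, dict] = {}
    kept, _ = filter_prediction_trials(pred_trials)
    lmm = accuracy_lmm_prediction(kept)
    p = lmm.pvalue("T." + direction)
    out["h1a"] = {
        "estimate": lmm.coef("T." + direction),
        "p": p,
        "reject": bool(p < alpha),
        "detail": lmm,
    }
    summaries = condition_summaries(kept, occlusions=main_occlusions)
    kept_sum, _ = filter_low_sd(summaries)
    lrt1 = precision_lrt_prediction(kept_sum, direction)
    out["h1b"] = {
        "estimate": lrt1.coefficient,
        "p": lrt1.p_value,
        "reject": bool(lrt1.p_value < alpha),
        "detail": lrt1,
    }
    if fits is None and speed_trials is not None:
        kept_stair, _ = filter_staircases(speed_trials)
        fits = fit_all(kept_stair)
    if fits is not None:
        lmm2 = pse_lmm(fits)
        p2 = lmm2.pvalue("T." + direction)
        out["h2a"] = {
            "estimate": lmm2.coef("T." + direction),
            "p": p2,
            "reject": bool(p2 < alpha),
            "detail": lmm2,
        }
        lrt2 = jnd_lrt(fits, direction)
        out["h2b"] = {
            "estimate": lrt2.coefficient,
            "p": lrt2.p_value,
            "reject": bool(lrt2.p_value < alpha),
            "detail": lrt2,
        }
        diffs = participant_differences(kept_sum, fits, direction)
        slope = bias_correlation(diffs)
        out["h3a"] = {
            "estimate": slope.slope,
            "p": slope.p_value,
            "reject": bool(slope.p_value < alpha),
            "detail": slope,
        }
        lrt3 = precision_link_lrt(diffs)
        out["h3b"] = {
            "estimate": lrt3.coefficient,
            "p": lrt3.p_value,
            "reject": bool(lrt3.p_value < alpha),
            "detail": lrt3,
        }
    return out
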