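"""Maximum-likelihood cumulative-Gaussian psychometric fits.

Choice probabilities are modelled as P(choose comparison | level x) =
Phi((x - pse) / jnd): a two-parameter fit with no lapse or guess rate.  The
mean of the fitted Gaussian is the point of subjective equality (PSE) and
its standard deviation is the 84.1% just-noticeable difference (JND).  Fits
maximise the Bernoulli likelihood directly with a bounded quasi-Newton
search from four deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

__all__ = ["PsychometricFit", "fit_cumulative_gaussian", "fit_all"]

_JND_FLOOR = 1e-3
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PsychometricFit:
    pse: float
    jnd: float
    neg_log_likelihood: float
    n_trials: int
    converged: bool
    message: str = ""


def _nll_grad(params, x, y):
    """Negative log-likelihood and its gradient wrt (pse, jnd)."""
    pse, jnd = params
    z = (x - pse) / jnd
    logp = log_ndtr(z)
    logq = log_ndtr(-z)
    nll = -(np.where(y, logp, logq)).sum()
    log_phi = -0.5 * z * z - _LOG_SQRT_2PI
    dnll_dz = np.where(y, -np.exp(log_phi - logp), np.exp(log_phi - logq))
    g_pse = (dnll_dz * (-1.0 / jnd)).sum()
    g_jnd = (dnll_dz * (-z / jnd)).sum()
    return nll, np.array([g_pse, g_jnd])


def fit_cumulative_gaussian(levels, chose_comparison) -> PsychometricFit:
    """Fit (PSE, JND) to binary 2IFC choices by direct likelihood maximisation.

    Needs at least 10 trials on at least 2 distinct levels.  Complete
    separation (or responses that never vary) drives the JND to its lower
    constraint; such fits are returned with ``converged=False`` and a
    diagnostic message rather than raising.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(chose_comparison, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responses must be matching 1-D sequences")
    if x.size < 10:
        raise ValueError("need at least 10 trials for a psychometric fit")
    if np.unique(x).size < 2:
        return PsychometricFit(
            pse=float(x[0]),
            jnd=_JND_FLOOR,
            neg_log_likelihood=float("nan"),
            n_trials=int(x.size),
            converged=False,
            message="single stimulus level",
        )
    spread = float(x.max() - x.min())
    sd = float(x.std()) or spread / 4.0
    mean = float(x.mean())
    jnd_hi = 3.0 * spread
    bounds = [(x.min() - 3.0 * spread, x.max() + 3.0 * spread), (_JND_FLOOR, jnd_hi)]
    starts = [
        (mean - sd, 0.5 * sd),
        (mean - sd, 1.5 * sd),
        (mean + sd, 0.5 * sd),
        (mean + sd, 1.5 * sd),
    ]
    best = None
    for p0 in starts:
        res = minimize(
            _nll_grad,
            np.clip(p0, [b[0] for b in bounds], [b[1] for b in bounds]),
            args=(x, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    pse, jnd = best.x
    message = ""
    converged = bool(best.success)
    if jnd <= _JND_FLOOR * (1 + 1e-6):
        converged = False
        message = "jnd at lower constraint (data separable)"
    elif jnd >= jnd_hi * (1 - 1e-6):
        converged = False
        message = "jnd at upper constraint"
    elif not y.any() or y.all():
        converged = False
        message = "responses never vary"
    elif not best.success:
        message = str(best.message)
    return PsychometricFit(
        pse=float(pse),
        jnd=float(jnd),
        neg_log_likelihood=float(best.fun),
        n_trials=int(x.size),
        converged=converged,
        message=message,
    )


def fit_all(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit one psychometric function per participant x speed x profile.

    Both staircases of a cell (the two start offsets) are pooled into a
    single fit.  Cells whose fit violates the preconditions are reported
    with ``converged=False`` instead of aborting the batch.
    """
    required = {"participant_id", "ball_speed_mps", "motion_profile", "cloud_speed_mps", "chose_cloud"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    rows = []
    for (pid, speed, prof), cell in trials.groupby(
        ["participant_id", "ball_speed_mps", "motion_profile"], sort=True
    ):
        try:
            fit = fit_cumulative_gaussian(
                cell["cloud_speed_mps"].to_numpy(), cell["chose_cloud"].to_numpy()
            )
        except ValueError as exc:
            fit = PsychometricFit(
                pse=float("nan"),
                jnd=float("nan"),
                neg_log_likelihood=float("nan"),
                n_trials=len(cell),
                converged=False,
                message=str(exc),
            )
        rows.append(
            {
                "participant_id": pid,
                "ball_speed_mps": speed,
                "motion_profile": prof,
                "pse_mps": fit.pse,
                "jnd_mps": fit.jnd,
                "nll": fit.neg_log_likelihood,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
                "message": fit.message,
            }
        )
    return pd.DataFrame(rows)


def fit_cumulative_gaussian_batch(cells: "list[tuple[np.ndarray, np.ndarray]]") -> np.ndarray:
    """Fit many psychometric cells at once; returns (n_cells, 2) [pse, jnd].

    Same maximum-likelihood problem as :func:`fit_cumulative_gaussian`, solved
    for all cells simultaneously by damped Newton iterations on
    (pse, log jnd) with finite-difference curvature of the analytic
    gradient.  Cells the Newton solver leaves with a non-negligible
    gradient are re-fit with the scalar routine.  Intended for the inner
    loop of simulation-based fitting, where hundreds of cells are fitted
    per objective evaluation.
    """
    n_cells = len(cells)
    if n_cells == 0:
        return np.empty((0, 2))
    width = max(len(c[0]) for c in cells)
    X = np.zeros((n_cells, width))
    Y = np.zeros((n_cells, width), dtype=bool)
    W = np.zeros((n_cells, width))
    for i, (x, y) in enumerate(cells):
        n = len(x)
        X[i, :n] = x
        Y[i, :n] = y
        W[i, :n] = 1.0
    counts = W.sum(1)
    mean = (X * W).sum(1) / counts
    var = (W * (X - mean[:, None]) ** 2).sum(1) / np.maximum(counts - 1, 1)
    sd = np.sqrt(np.maximum(var, 1e-4))
    spread = (np.where(W.astype(bool), X, -np.inf).max(1)
              - np.where(W.astype(bool), X, np.inf).min(1))
    jnd_lo, jnd_hi = _JND_FLOOR, 3.0 * np.maximum(spread, 1e-2)

    def nll_grad(pse, log_jnd):
        jnd = np.exp(log_jnd)
        z = (X - pse[:, None]) / jnd[:, None]
        logp = log_ndtr(z)
        logq = log_ndtr(-z)
        nll = -(W * np.where(Y, logp, logq)).sum(1)
        log_phi = -0.5 * z * z - _LOG_SQRT_2PI
        dnll_dz = W * np.where(Y, -np.exp(log_phi - logp), np.exp(log_phi - logq))
        g_pse = (dnll_dz * (-1.0 / jnd[:, None])).sum(1)
        g_ljnd = (dnll_dz * (-z)).sum(1)  # chain rule: dz/dlogjnd = -z
        return nll, g_pse, g_ljnd

    pse = mean.copy()
    ljnd = np.log(np.clip(sd, jnd_lo * 2, jnd_hi))
    f, gp, gj = nll_grad(pse, ljnd)
    lam = np.full(n_cells, 1e-3)
    h = 1e-5
    for _ in range(60):
        gnorm = np.hypot(gp, gj)
        active = gnorm > 1e-7 * np.maximum(counts, 1.0)
        if not active.any():
            break
        # finite-difference curvature of the gradient (2x2 per cell)
        _, gp1, gj1 = nll_grad(pse + h, ljnd)
        _, gp2, gj2 = nll_grad(pse, ljnd + h)
        h11 = (gp1 - gp) / h
        h12 = (gp2 - gp) / h
        h21 = (gj1 - gj) / h
        h22 = (gj2 - gj) / h
        h12 = 0.5 * (h12 + h21)
        a = h11 + lam
        d = h22 + lam
        det = a * d - h12 * h12
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        dp = -(d * gp - h12 * gj) / det
        dj = -(-h12 * gp + a * gj) / det
        step_ok = np.isfinite(dp) & np.isfinite(dj)
        dp = np.where(step_ok, dp, -gp)
        dj = np.where(step_ok, dj, -gj)
        # cap extreme steps
        dp = np.clip(dp, -spread, spread)
        dj = np.clip(dj, -2.0, 2.0)
        new_pse = np.where(active, pse + dp, pse)
        new_ljnd = np.clip(
            np.where(active, ljnd + dj, ljnd), np.log(jnd_lo), np.log(jnd_hi)
        )
        nf, ngp, ngj = nll_grad(new_pse, new_ljnd)
        improved = nf <= f + 1e-12
        take = active & improved
        pse = np.where(take, new_pse, pse)
        ljnd = np.where(take, new_ljnd, ljnd)
        f = np.where(take, nf, f)
        gp = np.where(take, ngp, gp)
        gj = np.where(take, ngj, gj)
        lam = np.where(take, np.maximum(lam / 3.0, 1e-5), lam * 4.0)
    out = np.column_stack([pse, np.exp(ljnd)])
    # polish the stragglers with the robust scalar fitter
    gnorm = np.hypot(gp, gj)
    rough = np.flatnonzero(gnorm > 1e-4 * np.maximum(counts, 1.0))
    for i in rough:
        x, y = cells[i]
        try:
            fit = fit_cumulative_gaussian(x, y)
            out[i] = (fit.pse, fit.jnd)
        except ValueError:
            pass
    return out
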