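"""Covariates-only null models and the per-subject residual scores.

The MDR cell classification is driven by a score vector computed once from
the outcome and clinical covariates, with no genotype involved:

* survival engine — martingale residuals of a covariates-only Cox model,
  ``s_i = delta_i - Lambda0(t_i) * exp(gamma' z_i)`` with the Breslow
  baseline cumulative hazard (Breslow tie handling throughout, so the
  residuals sum to zero identically);
* binary engine — score residuals ``s_i = y_i - p_i`` of a covariates-only
  logistic regression on the 5-year status (subjects censored before the
  horizon are excluded upstream).

A positive score means the subject did worse than the covariates predict;
cells accumulating positive score mass are labelled high-risk downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.duration.hazard_regression import PHReg

from .types import DataError, NoEventsError

__all__ = [
    "NullModel",
    "fit_cox_null",
    "martingale_residuals",
    "fit_logistic_null",
    "logistic_residual_scores",
    "scores_for_engine",
]


@dataclass
class NullModel:
    engine: str                      # "cox" or "logistic"
    coef: np.ndarray                 # gamma-hat (cox) / [intercept, beta] (logistic)
    coef_names: list
    loglik: float
    converged: bool
    ties: str = "breslow"
    baseline_times: np.ndarray | None = None      # cox: event times of Lambda0 steps
    baseline_cumhaz: np.ndarray | None = None     # cox: Lambda0 at those times
    fitted_probs: np.ndarray | None = None        # logistic: p-hat per subject


def _as_design(covariates) -> tuple[np.ndarray, list]:
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, [f"x{j}" for j in range(x.shape[1])]


def _check_full_rank(x: np.ndarray, with_intercept: bool) -> None:
    if x.size == 0:
        return
    design = np.column_stack([np.ones(len(x)), x]) if with_intercept else x
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError("covariate matrix is rank deficient (collinear columns)")


def breslow_baseline(time, event, eta) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline cumulative hazard given a linear predictor.

    Lambda0(t) = sum over event times t_j <= t of d_j / sum_{i in risk set} exp(eta_i).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    w_sorted = np.exp(eta[order])
    # risk-set weight for subject at sorted position i: sum of w from i to end
    rev_cumsum = np.cumsum(w_sorted[::-1])[::-1]
    event_times = np.unique(t_sorted[event[order] == 1])
    increments = np.empty(len(event_times))
    for idx, t in enumerate(event_times):
        d = np.sum((time == t) & (event == 1))
        first = np.searchsorted(t_sorted, t, side="left")
        increments[idx] = d / rev_cumsum[first]
    return event_times, np.cumsum(increments)


def fit_cox_null(time, event, covariates=None) -> NullModel:
    """Covariates-only proportional-hazards fit (Breslow ties + baseline)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise NoEventsError("no events in the data; cannot fit the null hazard model")
    x, names = _as_design(covariates)
    if x.size and len(x) != len(time):
        raise DataError("covariate rows do not match outcome length")
    _check_full_rank(x, with_intercept=False)
    if x.shape[1] if x.ndim == 2 else 0:
        model = PHReg(time, x, status=event, ties="breslow")
        rslt = model.fit(disp=False)
        coef = np.asarray(rslt.params)
        if not np.all(np.isfinite(coef)):
            raise DataError("Cox null model did not converge (non-finite coefficients)")
        loglik = float(model.loglike(coef))
        eta = x @ coef
    else:
        coef = np.empty(0)
        loglik = 0.0
        eta = np.zeros(len(time))
    bt, bh = breslow_baseline(time, event, eta)
    return NullModel(
        engine="cox",
        coef=coef,
        coef_names=names,
        loglik=loglik,
        converged=True,
        baseline_times=bt,
        baseline_cumhaz=bh,
    )


def martingale_residuals(model: NullModel, time, event, covariates=None) -> np.ndarray:
    """delta_i - Lambda0(t_i) exp(gamma' z_i); sums to zero by construction.

    Subjects with times beyond the last event time use the right-constant
    extension of the step-function baseline.
    """
    if model.engine != "cox":
        raise DataError("martingale residuals require the cox engine")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x, _ = _as_design(covariates)
    eta = x @ model.coef if model.coef.size else np.zeros(len(time))
    idx = np.searchsorted(model.baseline_times, time, side="right")
    cumhaz = np.concatenate([[0.0], model.baseline_cumhaz])[idx]
    return event - cumhaz * np.exp(eta)


def fit_logistic_null(status, covariates=None) -> NullModel:
    """Maximum-likelihood logistic fit with intercept, covariates only."""
    y = np.asarray(status, dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("binary outcome has a single class; cannot fit logistic null")
    x, names = _as_design(covariates)
    if x.size and len(x) != len(y):
        raise DataError("covariate rows do not match outcome length")
    _check_full_rank(x, with_intercept=True)
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    model = sm.Logit(y, design)
    try:
        rslt = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise DataError(f"logistic null model failed: {exc}") from exc
    if not rslt.mle_retvals.get("converged", False):
        raise DataError("logistic null model did not converge (separation?)")
    probs = np.asarray(rslt.predict(design))
    if np.any(probs <= 1e-10) or np.any(probs >= 1 - 1e-10):
        raise DataError("fitted probabilities degenerate (separation)")
    return NullModel(
        engine="logistic",
        coef=np.asarray(rslt.params),
        coef_names=["intercept"] + names,
        loglik=float(rslt.llf),
        converged=True,
        fitted_probs=probs,
    )


def logistic_residual_scores(model: NullModel, status) -> np.ndarray:
    """y_i - p_i; sums to zero because the fit includes an intercept."""
    if model.engine != "logistic":
        raise DataError("logistic residual scores require the logistic engine")
    y = np.asarray(status, dtype=float)
    if len(y) != len(model.fitted_probs):
        raise DataError("status length does not match the fitted model")
    return y - model.fitted_probs


def scores_for_engine(engine: str, covariates, time=None, event=None, status=None) -> np.ndarray:
    """Convenience: fit the null model for ``engine`` and return its scores."""
    if engine == "cox":
        model = fit_cox_null(time, event, covariates)
        return martingale_residuals(model, time, event, covariates)
    if engine == "logistic":
        model = fit_logistic_null(status, covariates)
        return logistic_residual_scores(model, status)
    raise DataError(f"unknown engine {engine!r}")
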