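"""Regression and Kaplan-Meier validation of a selected risk grouping.

After the MDR search and permutation testing select a model, its binary
high/low-risk grouping is checked against the outcome while adjusting for
the clinical covariates: a multivariable Cox model (hazard ratio, Wald 95%
CI and p) for the survival engine, a multivariable logistic model (odds
ratio) for the binary engine, plus product-limit curves and the two-sample
log-rank test. Cox fits use Breslow tie handling, consistent with the null
scoring model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .mdr import _cell_codes
from .types import DataError, GenotypeMatrix, KMResult, RegressionSummary, RiskModel

__all__ = [
    "assign_risk_groups",
    "cox_regression_validation",
    "logistic_regression_validation",
    "km_logrank",
]


def assign_risk_groups(geno, model: RiskModel) -> np.ndarray:
    """1 for subjects whose genotype cell the model labels high-risk.

    Cells absent from the model's high set — including cells never observed
    in training — default to low-risk.
    """
    if isinstance(geno, GenotypeMatrix):
        cols = [geno.col_index(s) for s in model.snp_ids]
        sub = geno.dosage[:, cols]
    else:
        sub = np.asarray(geno)[:, list(model.col_indices)]
    codes = _cell_codes(sub.astype(np.int8), np.arange(model.k, dtype=np.int64)[None, :])[:, 0]
    high_codes = {
        sum(g * 3 ** (model.k - 1 - j) for j, g in enumerate(cell)) for cell in model.high_cells
    }
    return np.isin(codes, sorted(high_codes)).astype(int)


def _design_with_group(group, covariates):
    group = np.asarray(group, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        x = covariates.to_numpy(dtype=float)
        names = list(covariates.columns)
    elif covariates is None:
        x = np.empty((len(group), 0))
        names = []
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{j}" for j in range(x.shape[1])]
    return np.column_stack([group, x]), ["risk_group"] + names


def _wald(beta: float, se: float):
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)), float(max(p, np.finfo(float).tiny))


def cox_regression_validation(
    group, covariates, time, event, direction: str = "low_vs_high"
) -> RegressionSummary:
    """Multivariable Cox fit of the risk grouping (Breslow ties).

    ``direction`` sets the reported contrast: "high_vs_low" reports the
    hazard ratio of the high-risk group, "low_vs_high" its reciprocal
    parameterisation (low-risk group as the indicator).
    """
    group = np.asarray(group, dtype=int)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(np.unique(group)) < 2:
        raise DataError("risk grouping has a single level")
    if event.sum() < 1:
        raise DataError("no events in the validation data")
    indicator = group if direction == "high_vs_low" else 1 - group
    design, names = _design_with_group(indicator, covariates)
    # partial likelihood is invariant to constant columns, so identifiability
    # requires full rank of [1, design]
    with_const = np.column_stack([np.ones(len(design)), design])
    if np.linalg.matrix_rank(with_const) < with_const.shape[1]:
        raise DataError("rank-deficient design (group collinear with a covariate?)")
    rslt = PHReg(time, design, status=event, ties="breslow").fit(disp=False)
    beta = np.asarray(rslt.params)
    se = np.asarray(rslt.bse)
    if not np.all(np.isfinite(beta)):
        raise DataError("validation Cox model did not converge")
    est, lo, hi, p = _wald(beta[0], se[0])
    return RegressionSummary(
        effect_type="HR",
        estimate=est,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        direction=direction,
        covariate_estimates={nm: float(np.exp(b)) for nm, b in zip(names[1:], beta[1:])},
        n_used=len(group),
    )


def logistic_regression_validation(
    group, covariates, status, direction: str = "high_vs_low"
) -> RegressionSummary:
    """Multivariable logistic fit of the risk grouping (odds ratio)."""
    group = np.asarray(group, dtype=int)
    y = np.asarray(status, dtype=int)
    if len(np.unique(group)) < 2:
        raise DataError("risk grouping has a single level")
    if len(np.unique(y)) < 2:
        raise DataError("binary outcome has a single class")
    indicator = group if direction == "high_vs_low" else 1 - group
    design, names = _design_with_group(indicator, covariates)
    design = np.column_stack([np.ones(len(y)), design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError("rank-deficient design (group collinear with a covariate?)")
    try:
        rslt = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise DataError(f"validation logistic model failed: {exc}") from exc
    if not rslt.mle_retvals.get("converged", False):
        raise DataError("validation logistic model did not converge (separation?)")
    beta = np.asarray(rslt.params)
    se = np.asarray(rslt.bse)
    est, lo, hi, p = _wald(beta[1], se[1])
    return RegressionSummary(
        effect_type="OR",
        estimate=est,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        direction=direction,
        covariate_estimates={nm: float(np.exp(b)) for nm, b in zip(names[1:], beta[2:])},
        n_used=len(y),
    )


def km_logrank(group, time, event) -> KMResult:
    """Product-limit curves per risk group and the two-sample log-rank test."""
    group = np.asarray(group, dtype=int)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    levels = np.unique(group)
    if len(levels) < 2:
        raise DataError("need two non-empty groups for the log-rank test")
    curves, censor_times = {}, {}
    for g in levels:
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        tab = kmf.event_table
        curves[int(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        censor_times[int(g)] = np.sort(time[mask & (event == 0)])
    res = logrank_test(
        time[group == levels[0]],
        time[group == levels[1]],
        event_observed_A=event[group == levels[0]],
        event_observed_B=event[group == levels[1]],
    )
    return KMResult(
        curves=curves,
        censor_times=censor_times,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )
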