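"""Linear elution models: OLS, AICc, forward stepwise selection, LOO.

The response is the molar NaCl concentration E required to elute a protein
from a multimodal cation-exchange resin; the predictors are the
occupancy-weighted descriptor aggregates of the protein's interaction
surface. Model search is greedy forward selection scored by the
small-sample-corrected Akaike information criterion

    AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n − k − 1),   k = p + 2

(intercept + p slopes + residual variance). Reported fit quality is
R² = 1 − SSE/SST and RMSE = √(SSE/DFE) with DFE = n − p − 1 error degrees
of freedom (√(SSE/n) available by flag). Validation is leave-one-out with
held-out prediction errors, and rank concordance of predicted vs observed
elution order (Kendall τ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SSE_FLOOR = 1e-12
CONDITION_LIMIT = 1e8


class RankDeficiencyError(ValueError):
    """Predictor matrix is (numerically) rank deficient."""


@dataclass
class ModelFit:
    response: str
    variables: list[str]
    intercept: float
    coefficients: dict[str, float]
    n: int
    r_squared: float
    rmse: float
    aicc: float | None
    fitted: np.ndarray
    residuals: np.ndarray
    sse: float
    rmse_convention: str = "dfe"

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def dfe(self) -> int:
        return self.n - self.p - 1


@dataclass
class StepwiseTrace:
    steps: list[ModelFit] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def selected(self) -> ModelFit:
        return self.steps[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.steps:
            rows.append(
                {
                    "AICc": m.aicc,
                    "R2": m.r_squared,
                    "RMSE": m.rmse,
                    "n_variables": m.p,
                    "DFE": m.dfe,
                    "variables": ", ".join(m.variables),
                }
            )
        return pd.DataFrame(rows)


def _design(X: pd.DataFrame, variables: list[str]) -> np.ndarray:
    mat = np.column_stack([np.ones(len(X))] + [X[v].to_numpy(float) for v in variables])
    if variables and np.linalg.cond(mat) > CONDITION_LIMIT:
        raise RankDeficiencyError(
            f"design matrix for {variables} has condition number > {CONDITION_LIMIT:.0e}"
        )
    return mat


def ols_fit(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    variables: list[str] | None = None,
    response: str = "E",
    rmse_convention: str = "dfe",
) -> ModelFit:
    """Ordinary least squares of *y* on the named columns of *X* (plus an
    intercept), via statsmodels.

    ``rmse_convention="dfe"`` gives RMSE = √(SSE/(n−p−1)); ``"n"`` gives the
    population form √(SSE/n).
    """
    import statsmodels.api as sm

    if variables is None:
        variables = list(X.columns)
    y = np.asarray(y, dtype=float)
    n = y.size
    p = len(variables)
    if n <= p + 1:
        raise ValueError(f"n = {n} observations cannot identify {p} slopes + intercept")
    design = _design(X, variables)
    res = sm.OLS(y, design).fit()
    sse = float(res.ssr)
    dfe = n - p - 1
    if rmse_convention == "dfe":
        rmse = float(np.sqrt(sse / dfe))
    elif rmse_convention == "n":
        rmse = float(np.sqrt(sse / n))
    else:
        raise ValueError(f"unknown RMSE convention {rmse_convention!r}")
    try:
        aicc_val = aicc(n, p, sse)
    except ValueError:
        aicc_val = None
    params = np.asarray(res.params)
    return ModelFit(
        response=response,
        variables=list(variables),
        intercept=float(params[0]),
        coefficients={v: float(c) for v, c in zip(variables, params[1:])},
        n=n,
        r_squared=float(res.rsquared) if p > 0 else 0.0,
        rmse=rmse,
        aicc=aicc_val,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        sse=sse,
        rmse_convention=rmse_convention,
    )


def aicc(n: int, p: int, sse: float, constant: bool = False) -> float:
    """Small-sample-corrected AIC for a Gaussian linear model with p slopes.

    k = p + 2 estimated parameters (intercept, slopes, residual variance);
    requires n − k − 1 > 0. SSE is floored at 1e-12 so perfect fits stay
    finite. By default the additive constant n·ln(2π) + n of the Gaussian
    −2·log-likelihood is dropped (it cancels in model comparison);
    ``constant=True`` includes it, matching the convention of common
    stepwise-regression software.
    """
    k = p + 2
    if n - k - 1 <= 0:
        raise ValueError(
            f"AICc undefined: n − k − 1 = {n - k - 1} ≤ 0 for n = {n}, p = {p}"
        )
    sse = max(float(sse), SSE_FLOOR)
    base = n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    if constant:
        base += n * np.log(2 * np.pi) + n
    return base


def stepwise_forward(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    response: str = "E",
    rmse_convention: str = "dfe",
    direction: str = "forward",
) -> StepwiseTrace:
    """Greedy forward selection minimising AICc.

    At each step the single variable whose addition gives the lowest AICc is
    added; the search stops when no addition lowers AICc, when the error
    degrees of freedom would drop below 1, or when AICc becomes undefined
    for the larger model. Ties are broken toward fewer variables, then by
    variable name. With ``direction="bidirectional"``, after every addition
    any single removal that lowers AICc further is applied (repeatedly)
    before the next addition is considered.
    """
    if direction not in ("forward", "bidirectional"):
        raise ValueError(f"unknown direction {direction!r}")
    if X.shape[1] == 0:
        raise ValueError("no candidate variables")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations for stepwise selection")
    candidates = sorted(X.columns)
    current: list[str] = []
    current_aicc = aicc(n, 0, float(((y - y.mean()) ** 2).sum()))
    trace = StepwiseTrace()
    while True:
        remaining = [v for v in candidates if v not in current]
        if not remaining:
            trace.stop_reason = "all variables included"
            break
        p_next = len(current) + 1
        if n - p_next - 1 < 1:
            trace.stop_reason = "error degrees of freedom exhausted"
            break
        try:
            aicc(n, p_next, 1.0)
        except ValueError:
            trace.stop_reason = "AICc undefined for larger model"
            break
        best: tuple[float, str, ModelFit] | None = None
        for v in remaining:  # lexicographic order → deterministic tie-break
            try:
                fit = ols_fit(X, y, current + [v], response=response,
                              rmse_convention=rmse_convention)
            except RankDeficiencyError:
                continue
            assert fit.aicc is not None
            if best is None or fit.aicc < best[0] - 1e-12:
                best = (fit.aicc, v, fit)
        if best is None:
            trace.stop_reason = "remaining variables rank deficient"
            break
        if best[0] < current_aicc - 1e-12:
            current = current + [best[1]]
            current_aicc = best[0]
            trace.steps.append(best[2])
            if direction == "bidirectional" and len(current) > 1:
                improved = True
                while improved and len(current) > 1:
                    improved = False
                    for v in sorted(current):
                        reduced = [w for w in current if w != v]
                        fit = ols_fit(X, y, reduced, response=response,
                                      rmse_convention=rmse_convention)
                        if fit.aicc is not None and fit.aicc < current_aicc - 1e-12:
                            current = reduced
                            current_aicc = fit.aicc
                            trace.steps.append(fit)
                            improved = True
                            break
        else:
            trace.stop_reason = "no addition lowers AICc"
            break
    if not trace.steps:
        # keep the trace non-empty: record the null (intercept-only) model
        sse0 = float(((y - y.mean()) ** 2).sum())
        trace.steps.append(
            ModelFit(
                response=response, variables=[], intercept=float(y.mean()),
                coefficients={}, n=n, r_squared=0.0,
                rmse=float(np.sqrt(sse0 / (n - 1))), aicc=current_aicc,
                fitted=np.full(n, y.mean()), residuals=y - y.mean(), sse=sse0,
                rmse_convention=rmse_convention,
            )
        )
        if not trace.stop_reason:
            trace.stop_reason = "no variable improves on the null model"
    return trace


def leave_one_out(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    variables: list[str],
    response: str = "E",
) -> pd.DataFrame:
    """Refit the model n times, each omitting one observation.

    Returns one row per fold: the omitted id, per-fold intercept and
    coefficients, fold R² and RMSE, and the held-out prediction error
    y_i − ŷ_(−i)(x_i). Rank-deficient folds are flagged, not fatal.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < len(variables) + 3:
        raise ValueError("too few observations for leave-one-out with this model")
    ids = list(X.index)
    rows = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi = X.iloc[mask]
        yi = y[mask]
        row: dict = {"omitted": ids[i]}
        try:
            fit = ols_fit(Xi, yi, variables, response=response)
            pred = predict_elution(fit, X.iloc[i])
            row.update(
                intercept=fit.intercept,
                **{f"coef_{v}": fit.coefficients[v] for v in variables},
                R2=fit.r_squared,
                RMSE=fit.rmse,
                prediction=pred,
                heldout_error=y[i] - pred,
                flag="",
            )
        except (RankDeficiencyError, ValueError) as exc:
            row.update(flag=f"rank-deficient fold: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def predict_elution(fit: ModelFit, aggregates) -> float:
    """E = intercept + Σ coef·aggregate for one protein's descriptor row."""
    get = aggregates.get if hasattr(aggregates, "get") else None
    total = fit.intercept
    for v, c in fit.coefficients.items():
        if get is not None:
            val = get(v)
            if val is None:
                raise KeyError(f"aggregate for variable {v!r} missing")
        else:
            val = aggregates[v]
        total += c * float(val)
    return float(total)


def rank_concordance(predicted, observed) -> tuple[float, bool]:
    """Kendall τ between predicted and observed elution concentrations, and
    whether the predicted order is exactly right (τ == 1)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size:
        raise ValueError("length mismatch between predicted and observed")
    if predicted.size < 2:
        raise ValueError("need at least two proteins")
    if np.unique(observed).size != observed.size:
        raise ValueError("observed elution concentrations contain ties")
    tau = float(stats.kendalltau(predicted, observed).statistic)
    return tau, bool(abs(tau - 1.0) < 1e-12)
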