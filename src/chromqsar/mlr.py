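"""Multiple linear regression engine for QSAR model fitting.

Models are ordinary least squares with intercept,

    y = b0 + b1 x1 + ... + bp xp + e,

relating a pharmacokinetic response (log K_p, log K_a,HSA, log BB,
Caco-2, f_u,brain) to lipophilic (log k_m, log k_0.1, log k_w),
structural (MW, TPSA) and electronic (polarizability) descriptors.
Reported global statistics follow the conventions of standard QSAR
tables: R^2, adjusted R^2, residual standard deviation
sd = sqrt(SSE/(n-p-1)), the overall F statistic and its p-value.

Fitting is delegated to statsmodels' QR/pinv-based OLS; an explicit
normal-equations solve exists only as an independent oracle in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import CompoundTable
from .errors import (
    CollinearityError,
    DataValidationError,
    InsufficientDataError,
    MissingPredictorError,
)

__all__ = ["ModelSpec", "MlrModel", "fit_mlr", "predict", "standardized_coefficients"]


@dataclass(frozen=True)
class ModelSpec:
    """Which response to model on which descriptors, plus a display label."""

    response: str
    predictors: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.predictors:
            raise DataValidationError("ModelSpec needs at least one predictor")
        if len(set(self.predictors)) != len(self.predictors):
            raise DataValidationError("ModelSpec predictors must be unique")
        if self.response in self.predictors:
            raise DataValidationError("response cannot appear among predictors")
        object.__setattr__(self, "predictors", tuple(self.predictors))

    def formula(self) -> str:
        return f"{self.response} ~ {' + '.join(self.predictors)}"


@dataclass
class MlrModel:
    """A fitted OLS model with its design kept for downstream diagnostics."""

    spec: ModelSpec
    n: int
    params: pd.Series          # intercept ('const') first
    bse: pd.Series             # standard errors, same index
    r_squared: float
    adj_r_squared: float
    sd_resid: float            # residual standard error, response units
    f_stat: float
    p_value: float
    fitted: pd.Series
    residuals: pd.Series
    design: pd.DataFrame = field(repr=False)   # columns: const + predictors
    y: pd.Series = field(repr=False)

    @property
    def p(self) -> int:
        return len(self.spec.predictors)

    def coefficient_string(self, decimals: int = 3) -> str:
        """Human-readable 'est(se)' equation string."""
        terms = [f"{self.params['const']:.{decimals}f}({self.bse['const']:.{decimals}f})"]
        for name in self.spec.predictors:
            b, se = self.params[name], self.bse[name]
            terms.append(f"{b:+.{decimals}f}({se:.{decimals}f})*{name}")
        return f"{self.spec.response} = " + " ".join(terms)


def _design_frame(table: CompoundTable, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    frame = table.to_frame()
    missing = [c for c in (*spec.predictors, spec.response) if c not in frame.columns]
    if missing:
        raise MissingPredictorError(
            f"table is missing column(s) {missing} required by {spec.formula()!r}"
        )
    cols = frame[list(spec.predictors) + [spec.response]].apply(pd.to_numeric)
    cols = cols.dropna()  # pairwise-complete cases for this model
    y = cols[spec.response]
    X = sm.add_constant(cols[list(spec.predictors)], has_constant="add")
    return X, y


def fit_mlr(table: CompoundTable, spec: ModelSpec) -> MlrModel:
    """Fit OLS with intercept; raises on rank deficiency or n <= p + 1."""
    X, y = _design_frame(table, spec)
    n, pp1 = X.shape
    if n <= pp1:
        raise InsufficientDataError(
            f"{spec.formula()}: need n > p + 1 = {pp1}, have n = {n} complete compounds"
        )
    rank = np.linalg.matrix_rank(X.values)
    if rank < pp1:
        # identify columns involved in the dependency via near-zero
        # singular directions
        _, s, vt = np.linalg.svd(X.values)
        null = vt[rank:]
        involved = [
            c for j, c in enumerate(X.columns) if np.any(np.abs(null[:, j]) > 1e-8)
        ]
        raise CollinearityError(
            f"{spec.formula()}: design matrix is rank deficient "
            f"(rank {rank} < {pp1}); dependent columns: {involved}"
        )
    res = sm.OLS(y, X).fit()
    p = pp1 - 1
    sd_resid = float(np.sqrt(res.ssr / (n - p - 1)))
    return MlrModel(
        spec=spec,
        n=n,
        params=res.params,
        bse=res.bse,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        sd_resid=sd_resid,
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        fitted=res.fittedvalues,
        residuals=res.resid,
        design=X,
        y=y,
    )


def predict(model: MlrModel, table: CompoundTable) -> pd.Series:
    """Apply a fitted model's coefficients to (possibly new) compounds."""
    frame = table.to_frame()
    missing = [c for c in model.spec.predictors if c not in frame.columns]
    if missing:
        raise MissingPredictorError(f"prediction requires missing column(s) {missing}")
    X = frame[list(model.spec.predictors)].apply(pd.to_numeric)
    pred = model.params["const"] + X.mul(model.params[list(model.spec.predictors)]).sum(
        axis=1, skipna=False
    )
    pred.name = model.spec.response
    return pred


def standardized_coefficients(model: MlrModel, table: CompoundTable | None = None) -> pd.Series:
    """Standardized betas b_j * s(x_j) / s(y) over the training rows.

    These are the dimensionless coefficients a fit on z-scored data would
    produce; the intercept is excluded. Sample standard deviations
    (ddof=1) are used.
    """
    X = model.design[list(model.spec.predictors)]
    sy = float(model.y.std(ddof=1))
    betas = {}
    for name in model.spec.predictors:
        sx = float(X[name].std(ddof=1))
        if sx == 0.0:
            raise DataValidationError(f"predictor {name!r} has zero variance")
        betas[name] = float(model.params[name]) * sx / sy
    return pd.Series(betas, name="std_beta")
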