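"""Leave-one-out cross-validation and collinearity diagnostics.

PRESS (predicted residual sum of squares) uses the hat-matrix shortcut:
for OLS the deleted residual of observation i equals e_i / (1 - h_ii),
so no refitting is needed.  Q^2 = 1 - PRESS / SS_total (SS_total about
the full-sample response mean) is the cross-validated analogue of R^2;
Q^2 < R^2 strictly whenever the full fit leaves any residual error.

VIF_j = 1 / (1 - R_j^2), with R_j^2 from regressing predictor j on the
remaining predictors (with intercept), quantifies collinearity; values
below 5 are conventionally considered unproblematic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import CompoundTable
from .errors import (
    CollinearityError,
    DataValidationError,
    DegenerateFitError,
    InsufficientDataError,
    MissingPredictorError,
)
from .mlr import MlrModel, ModelSpec

__all__ = ["ValidationReport", "loo_validate", "compute_vif", "hat_diagonal"]


@dataclass
class ValidationReport:
    label: str
    press: float                 # sum of squared deleted residuals
    mse_resid: float             # residual mean square, sd_resid^2
    mse_cv: float                # PRESS / n
    q_squared: float             # 1 - PRESS / SS_total
    loo_residuals: pd.Series     # per-compound deleted residuals
    vif: pd.Series               # per-predictor variance inflation factors


def hat_diagonal(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Diagonal of H = X (X'X)^-1 X' via the pseudo-inverse."""
    Xv = np.asarray(X, dtype=float)
    # row-wise: h_ii = x_i' (X'X)^-1 x_i
    XtX_inv = np.linalg.pinv(Xv.T @ Xv)
    return np.einsum("ij,jk,ik->i", Xv, XtX_inv, Xv)


def loo_validate(model: MlrModel, table: CompoundTable | None = None) -> ValidationReport:
    """Leave-one-out validation of a fitted model via the hat-matrix shortcut."""
    n, p = model.n, model.p
    if n <= p + 2:
        raise InsufficientDataError(
            f"{model.spec.formula()}: LOO validation needs n > p + 2, have n = {n}"
        )
    h = hat_diagonal(model.design)
    degenerate = np.isclose(h, 1.0)
    if degenerate.any():
        bad = list(model.design.index[degenerate])
        raise DegenerateFitError(
            f"leverage of compound(s) {bad} equals 1; deleted residual undefined"
        )
    deleted = model.residuals / (1.0 - h)
    press = float(np.sum(deleted**2))
    sst = float(np.sum((model.y - model.y.mean()) ** 2))
    q2 = 1.0 - press / sst
    if table is not None:
        vif = compute_vif(table, model.spec)
    else:
        vif = _vif_from_design(model.design[list(model.spec.predictors)])
    return ValidationReport(
        label=model.spec.label or model.spec.formula(),
        press=press,
        mse_resid=model.sd_resid**2,
        mse_cv=press / n,
        q_squared=q2,
        loo_residuals=deleted.rename("loo_residual"),
        vif=vif,
    )


def _vif_from_design(X: pd.DataFrame) -> pd.Series:
    if X.shape[1] < 2:
        return pd.Series(
            {c: 1.0 for c in X.columns}, name="vif", dtype=float
        )
    out = {}
    for col in X.columns:
        others = [c for c in X.columns if c != col]
        aux = sm.OLS(X[col], sm.add_constant(X[others], has_constant="add")).fit()
        r2 = float(aux.rsquared)
        if r2 >= 1.0 - 1e-12:
            raise CollinearityError(
                f"predictor {col!r} is perfectly explained by {others}; VIF infinite"
            )
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def compute_vif(table: CompoundTable, spec: ModelSpec) -> pd.Series:
    """Variance inflation factors for a model spec's predictors on a table."""
    if len(spec.predictors) < 2:
        raise DataValidationError("VIF needs at least 2 predictors")
    frame = table.to_frame()
    missing = [c for c in spec.predictors if c not in frame.columns]
    if missing:
        raise MissingPredictorError(f"table is missing predictor column(s) {missing}")
    X = frame[list(spec.predictors)].apply(pd.to_numeric).dropna()
    return _vif_from_design(X)


def validation_frame(reports: list[ValidationReport], models: dict[str, MlrModel]) -> pd.DataFrame:
    """Summary table: one row per model (adj R^2, PRESS, MSE, Q^2, max VIF)."""
    rows = {}
    for rep in reports:
        model = models.get(rep.label)
        rows[rep.label] = {
            "adj_r_squared": model.adj_r_squared if model else np.nan,
            "press": rep.press,
            "mse_resid": rep.mse_resid,
            "q_squared": rep.q_squared,
            "mse_cv": rep.mse_cv,
            "max_vif": float(rep.vif.max()),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "label"
    return frame
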