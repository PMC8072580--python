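"""Applicability-domain analysis via leverage (Williams plot data).

A QSAR model is only trustworthy for compounds structurally similar to
its training set.  The leverage h_ii (diagonal of the hat matrix of the
model design, intercept included) measures how far compound i sits from
the descriptor centroid; the warning leverage

    h* = 3 (k + 1) / n

(k descriptors, n training compounds) is the conventional cutoff.
Compounds with h_ii > h* are structural outliers; compounds whose
standardized residual |e_i / (sd * sqrt(1 - h_ii))| exceeds 3 are
response outliers.  Plotting standardized residual against leverage with
these two cutoffs is the Williams plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError, DegenerateFitError
from .mlr import MlrModel
from .validation import hat_diagonal

__all__ = ["AdReport", "warning_leverage", "williams_data"]

#: Conventional Williams-plot band for standardized residuals.
RESIDUAL_CUTOFF = 3.0


@dataclass
class AdReport:
    label: str
    h_star: float
    leverages: pd.Series
    std_residuals: pd.Series
    leverage_outliers: list[str]
    residual_outliers: list[str]
    residual_cutoff: float = RESIDUAL_CUTOFF

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"leverage": self.leverages, "std_residual": self.std_residuals}
        )
        out["leverage_outlier"] = out.index.isin(self.leverage_outliers)
        out["residual_outlier"] = out.index.isin(self.residual_outliers)
        out.index.name = "compound_id"
        return out


def warning_leverage(k: int, n: int) -> float:
    """h* = 3(k+1)/n for a model with k descriptors fitted on n compounds."""
    if k < 1:
        raise DataValidationError(f"descriptor count k must be >= 1, got {k}")
    if n <= k + 1:
        raise DataValidationError(
            f"need more observations than parameters: n = {n} <= k + 1 = {k + 1}"
        )
    return 3.0 * (k + 1) / n


def williams_data(
    model: MlrModel,
    residual_cutoff: float = RESIDUAL_CUTOFF,
) -> AdReport:
    """Leverages, standardized residuals and outlier flags for a fitted model.

    Standardized residuals are internally studentized:
    e_i / (sd_resid * sqrt(1 - h_ii)).
    """
    scale = max(1.0, float(np.sqrt(np.mean(np.square(model.y)))))
    if model.sd_resid <= 1e-12 * scale:
        raise DegenerateFitError(
            f"{model.spec.formula()}: residual sd is (numerically) 0; "
            "standardized residuals undefined"
        )
    h = pd.Series(hat_diagonal(model.design), index=model.design.index, name="leverage")
    h_star = warning_leverage(model.p, model.n)
    std = model.residuals / (model.sd_resid * np.sqrt(1.0 - h))
    std.name = "std_residual"
    return AdReport(
        label=model.spec.label or model.spec.formula(),
        h_star=h_star,
        leverages=h,
        std_residuals=std,
        leverage_outliers=list(h.index[h > h_star]),
        residual_outliers=list(std.index[np.abs(std) > residual_cutoff]),
        residual_cutoff=residual_cutoff,
    )
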