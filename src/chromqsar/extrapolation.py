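"""Isocratic extrapolation of log k_w from organic-modifier series.

On reversed-phase columns the retention factor of a solute decreases
log-linearly with the volume fraction phi of organic modifier
(acetonitrile here):

    log10 k = log10 k_w - S * phi

log k_w, the intercept at phi = 0 (pure aqueous eluent), is the classical
RPLC lipophilicity descriptor; S is the (positive) solvent-strength
sensitivity.  The fit is OLS of log10 k on phi over an isocratic series,
typically phi = 0.2-0.5 in steps of 0.1, so log k_w is an extrapolation
well outside the sampled range and its standard error (``se_log_kw``)
grows with that distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import CompoundTable, RetentionSeries
from .errors import DataValidationError, InsufficientDataError

__all__ = ["ExtrapolationFit", "fit_log_kw", "fit_log_kw_batch"]


@dataclass
class ExtrapolationFit:
    log_kw: float      # intercept at phi = 0, base-10 log units
    s_slope: float     # positive sensitivity S (= minus the fitted slope)
    r_squared: float
    n_points: int
    se_log_kw: float   # standard error of the extrapolated intercept


def fit_log_kw(series: RetentionSeries) -> ExtrapolationFit:
    """OLS of log10 k against modifier volume fraction; intercept = log k_w."""
    if series.x_kind != "modifier_volume_fraction":
        raise DataValidationError(
            f"log k_w extrapolation requires a modifier-fraction series, got {series.x_kind!r}"
        )
    if len(series) < 3:
        raise InsufficientDataError(
            f"compound {series.compound_id}: log k_w fit needs >= 3 points, got {len(series)}"
        )
    y = np.log10(series.k)
    res = stats.linregress(series.x, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else float(res.rvalue ** 2)
    se = float(res.intercept_stderr) if sst > 0 else 0.0
    return ExtrapolationFit(
        log_kw=float(res.intercept),
        s_slope=-float(res.slope),
        r_squared=r2,
        n_points=len(series),
        se_log_kw=se,
    )


def fit_log_kw_batch(table: CompoundTable, system: str = "IAM") -> dict[str, ExtrapolationFit]:
    """Fit log k_w for every compound with a series on ``system`` (IAM or ODS).

    Results are stored on the table as the derived descriptor
    ``log_kw_iam`` or ``log_kw_ods``.
    """
    fits: dict[str, ExtrapolationFit] = {}
    for cid in table.compound_ids:
        series = table.get_series(cid, system)
        if series is not None:
            fits[cid] = fit_log_kw(series)
    name = f"log_kw_{system.lower()}"
    existing = dict(table.derived_descriptors.get(name, {}))
    existing.update({cid: f.log_kw for cid, f in fits.items()})
    if existing:
        table.set_derived(name, existing)
    return fits
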