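"""Solute-micelle binding fits for micellar liquid chromatography.

In MLC the retention factor k falls as the micelle concentration [M]
rises.  The Foley model linearizes this as

    1/k = 1/k_m + (K_AM / k_m) [M]

where k_m is the retention factor extrapolated to zero micelle
concentration (the micellar lipophilicity descriptor, reported as
log10 k_m) and K_AM (L/mol) is the solute-micelle binding constant.  Both
come from an unweighted OLS of 1/k against [M]; [M] is the total
surfactant molarity minus the critical micelle concentration (CMC).

The CMC defaults to 0: for Brij 35 it is ~9e-5 mol/L, negligible against
the 0.075-0.150 mol/L working range, and the bundled dataset's published
log k_m column is reproduced without the subtraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import CompoundTable, RetentionSeries
from .errors import DataValidationError, DegenerateFitError, InsufficientDataError

__all__ = ["FoleyFit", "FoleyBatchResult", "fit_foley", "fit_foley_batch"]


@dataclass
class FoleyFit:
    """Result of fitting the linearized Foley model to one retention series.

    ``intercept`` and ``slope`` are on the transformed (1/k vs [M]) scale;
    ``km = 1/intercept`` and ``k_am = slope/intercept`` recover the model
    parameters, ``log_km = log10(km)``.  ``negative_intercept`` marks fits
    whose raw intercept was <= 0 (strong binders measured far from [M]=0);
    there ``km`` is taken from the intercept magnitude, which is how the
    published descriptor values for such compounds were evidently obtained,
    and the fit should be treated with caution.
    """

    km: float
    k_am: float
    log_km: float
    intercept: float
    slope: float
    r_squared: float
    n_points: int
    negative_intercept: bool = False


@dataclass
class FoleyBatchResult:
    fits: dict[str, FoleyFit]
    failures: dict[str, str]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS; returns (slope, intercept, r_squared).

    R^2 of a constant-y series is defined as 1 (the line reproduces the
    data exactly).
    """
    res = stats.linregress(x, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return float(res.slope), float(res.intercept), 1.0
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def fit_foley(
    series: RetentionSeries,
    cmc: float = 0.0,
    *,
    strict: bool = False,
) -> FoleyFit:
    """Fit 1/k = 1/k_m + (K_AM/k_m)([M] - CMC) by unweighted OLS.

    Parameters
    ----------
    series
        Micellar retention series (``x_kind == 'surfactant_molarity'``).
    cmc
        Critical micelle concentration (mol/L) subtracted from each
        surfactant concentration. Default 0.
    strict
        If True, a fitted intercept <= 0 raises DegenerateFitError instead
        of falling back to the intercept magnitude.
    """
    if series.x_kind != "surfactant_molarity":
        raise DataValidationError(
            f"Foley fit requires surfactant molarity series, got {series.x_kind!r}"
        )
    if len(series) < 3:
        raise InsufficientDataError(
            f"compound {series.compound_id}: Foley fit needs >= 3 points, got {len(series)}"
        )
    m = series.x - cmc
    if np.any(m <= 0):
        raise DataValidationError(
            f"compound {series.compound_id}: all concentrations must exceed the CMC ({cmc} mol/L)"
        )
    slope, intercept, r2 = _ols_line(m, 1.0 / series.k)
    negative = intercept <= 0
    if negative and strict:
        raise DegenerateFitError(
            f"compound {series.compound_id}: fitted 1/k intercept {intercept:.3g} <= 0, "
            "k_m undefined"
        )
    if intercept == 0:
        raise DegenerateFitError(
            f"compound {series.compound_id}: fitted 1/k intercept is exactly 0"
        )
    if negative:
        warnings.warn(
            f"compound {series.compound_id}: negative Foley intercept "
            f"({intercept:.3g}); using its magnitude for k_m",
            RuntimeWarning,
            stacklevel=2,
        )
    km = 1.0 / abs(intercept)
    k_am = slope / abs(intercept)
    return FoleyFit(
        km=km,
        k_am=k_am,
        log_km=math.log10(km),
        intercept=intercept,
        slope=slope,
        r_squared=r2,
        n_points=len(series),
        negative_intercept=bool(negative),
    )


def fit_foley_batch(
    table: CompoundTable,
    cmc: float = 0.0,
    *,
    strict: bool = False,
) -> FoleyBatchResult:
    """Foley-fit every compound's MLC series; store log_km on the table.

    Per-compound failures (missing series, degenerate fits) are collected
    in ``failures`` keyed by compound_id; the batch continues.
    """
    fits: dict[str, FoleyFit] = {}
    failures: dict[str, str] = {}
    for cid in table.compound_ids:
        series = table.get_series(cid, "MLC")
        if series is None:
            failures[cid] = "no MLC retention series"
            continue
        try:
            fits[cid] = fit_foley(series, cmc, strict=strict)
        except Exception as exc:  # noqa: BLE001 - reported per compound
            failures[cid] = str(exc)
    # merge so pre-supplied log_km values for unfitted compounds survive
    merged = dict(table.derived_descriptors.get("log_km", {}))
    merged.update({cid: f.log_km for cid, f in fits.items()})
    if merged:
        table.set_derived("log_km", merged)
    return FoleyBatchResult(fits=fits, failures=failures)


def foley_batch_frame(result: FoleyBatchResult):
    """Batch result as a DataFrame (compound_id, km, k_am, log_km, r_squared, n_points)."""
    import pandas as pd

    rows = {
        cid: {
            "km": f.km,
            "k_am": f.k_am,
            "log_km": f.log_km,
            "r_squared": f.r_squared,
            "n_points": f.n_points,
            "negative_intercept": f.negative_intercept,
        }
        for cid, f in result.fits.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "compound_id"
    return frame
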