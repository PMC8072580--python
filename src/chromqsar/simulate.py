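"""Synthetic data generators mirroring the statistical structure of the pipeline.

Two forward models are provided:

* :func:`gen_foley_series` draws micellar retention series from
  k(x) = km / (1 + K_AM x) with multiplicative lognormal noise —
  retention factors are positive and ratio-scaled, so noise is most
  naturally a relative (CV) perturbation.

* :func:`gen_qsar_table` draws descriptor tables with a linear response
  plus additive Gaussian noise — the assumption under which OLS and its
  standard errors are exact.

Defaults mirror the bundled 19-congener study: four Brij 35 molarities
0.075-0.150 mol/L, descriptor ranges spanning the observed table
(mw 256-356 g/mol, tpsa 48-75 A^2, alpha 25-34 A^3, log_km 0.3-2.9) and
the log K_p model's coefficients and residual sd as generating truth.
Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import CompoundRecord, CompoundTable, RetentionSeries
from .errors import DataValidationError

__all__ = ["FoleyTruth", "QsarTruth", "gen_foley_series", "gen_qsar_table"]

#: Brij 35 working concentrations of the emulated study, mol/L.
DEFAULT_CONCENTRATIONS = (0.075, 0.100, 0.125, 0.150)

#: log K_p model truth: intercept and per-descriptor slopes.
DEFAULT_COEFFICIENTS = {
    "const": -7.137,
    "log_km": 0.272,
    "tpsa": -0.025,
    "alpha": 0.041,
    "mw": 0.003,
}

#: Uniform sampling bounds spanning the observed descriptor table.
DEFAULT_RANGES = {
    "log_km": (0.3, 2.9),
    "tpsa": (48.0, 75.0),
    "alpha": (25.0, 34.0),
    "mw": (256.0, 356.0),
}


@dataclass
class FoleyTruth:
    """Generating parameters for one micellar retention series."""

    km: float = 50.0
    k_am: float = 20.0           # L/mol
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    noise_cv: float = 0.0        # lognormal coefficient of variation on k
    seed: int = 0

    def validate(self) -> None:
        if not (self.km > 0):
            raise DataValidationError(f"km must be > 0, got {self.km}")
        if self.k_am < 0:
            raise DataValidationError(f"k_am must be >= 0, got {self.k_am}")
        if self.noise_cv < 0:
            raise DataValidationError(f"noise_cv must be >= 0, got {self.noise_cv}")


@dataclass
class QsarTruth:
    """Generating parameters for a descriptor/response table."""

    n_compounds: int = 19
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    noise_sd: float = 0.108      # response units; the emulated model's residual sd
    response: str = "log_Kp"
    correlation: float = 0.0     # equicorrelation of descriptors (Gaussian copula)
    seed: int = 0

    @property
    def descriptors(self) -> list[str]:
        return [n for n in self.coefficients if n != "const"]

    def validate(self) -> None:
        k = len(self.descriptors)
        if self.n_compounds <= k + 2:
            raise DataValidationError(
                f"n_compounds must exceed descriptor count + 2 ({k + 2}), got {self.n_compounds}"
            )
        if self.noise_sd < 0:
            raise DataValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (-1.0 < self.correlation < 1.0):
            raise DataValidationError("correlation must lie in (-1, 1)")
        missing = set(self.descriptors) - set(self.descriptor_ranges)
        if missing:
            raise DataValidationError(f"no sampling range for descriptor(s) {sorted(missing)}")


def gen_foley_series(truth: FoleyTruth, compound_id: str = "sim") -> RetentionSeries:
    """Draw one micellar series k_i = km/(1 + K_AM x_i) * lognormal noise.

    The lognormal factor has unit mean and coefficient of variation
    ``noise_cv``, so retention stays positive and E[k] equals the model
    curve.
    """
    truth.validate()
    x = np.asarray(truth.concentrations, dtype=float)
    k = truth.km / (1.0 + truth.k_am * x)
    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2))
        k = k * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=k.shape)
    return RetentionSeries(
        compound_id=compound_id,
        system="MLC",
        x_kind="surfactant_molarity",
        x=x,
        k=k,
    )


def gen_qsar_table(truth: QsarTruth) -> CompoundTable:
    """Draw a descriptor table with linear response + Gaussian noise.

    Descriptors are sampled uniformly within their ranges, independently
    by default; ``truth.correlation`` imposes an equicorrelated Gaussian
    copula to emulate the collinearity of real descriptor tables (and to
    exercise VIF diagnostics).
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    names = truth.descriptors
    d = len(names)
    n = truth.n_compounds
    if truth.correlation != 0.0:
        cov = np.full((d, d), truth.correlation)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(d), cov, size=n, method="cholesky")
        u = stats.norm.cdf(z)
    else:
        u = rng.uniform(size=(n, d))
    X = np.empty((n, d))
    for j, name in enumerate(names):
        lo, hi = truth.descriptor_ranges[name]
        X[:, j] = lo + u[:, j] * (hi - lo)
    y = truth.coefficients["const"] + X @ np.array([truth.coefficients[c] for c in names])
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=n)

    records = []
    derived: dict[str, dict[str, float]] = {}
    structural = {"mw", "tpsa", "alpha"}
    for i in range(n):
        cid = f"sim{i + 1}"
        vals = dict(zip(names, X[i]))
        rec = CompoundRecord(
            compound_id=cid,
            series="sim",
            mw=vals.get("mw", 300.0),
            tpsa=vals.get("tpsa", 60.0),
            alpha=vals.get("alpha", 30.0),
            responses={truth.response: float(y[i])},
        )
        records.append(rec)
        for name in names:
            if name not in structural:
                derived.setdefault(name, {})[cid] = float(vals[name])
    table = CompoundTable(records=records, derived_descriptors=derived)
    table.validate()
    return table
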