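"""End-to-end runner: retention fits -> descriptor table -> MLR -> validation -> AD.

``run_pipeline`` executes the whole workflow on the bundled dataset or on
user-supplied compound/retention tables and writes per-model reports
(coefficient table, validation table, applicability-domain table), the
optional figures, and one machine-readable JSON summary.  In
``reproduce`` mode every refitted statistic is additionally compared
cell-by-cell against the published reference values bundled in
:mod:`chromqsar.reference`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CompoundTable, load_bundled_dataset, read_compound_table
from .domain import AdReport, williams_data
from .errors import ChromQsarError, DataValidationError
from .foley import fit_foley_batch
from .mlr import MlrModel, ModelSpec, fit_mlr, standardized_coefficients
from .reference import (
    FOLEY_LOG_KM_TOL,
    FOLEY_R2_TOL,
    MODEL_SPECS,
    REFERENCE_FOLEY,
    REFERENCE_MODELS,
    printed_tolerance,
    printed_value,
)
from .validation import ValidationReport, loo_validate

logger = logging.getLogger("chromqsar.pipeline")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "eluent_correlation_report",
           "reproduce_reference"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    compound_path: str | None = None      # None -> bundled dataset
    retention_path: str | None = None
    cmc: float = 0.0                      # surfactant CMC, mol/L
    model_specs: list[ModelSpec] = field(default_factory=lambda: list(MODEL_SPECS))
    output_dir: str | None = None
    make_figures: bool = False
    reproduce: bool = False               # compare against published reference values
    tolerance_factor: float = 1.5         # units of last printed decimal
    seed: int = 0                         # used only by synthetic stages

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a JSON file; model specs as {response, predictors, label}."""
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        specs = [
            ModelSpec(m["response"], tuple(m["predictors"]), m.get("label", ""))
            for m in raw.get("model_specs", [])
        ] or list(MODEL_SPECS)
        return cls(
            compound_path=raw.get("compound_path"),
            retention_path=raw.get("retention_path"),
            cmc=float(raw.get("cmc", 0.0)),
            model_specs=specs,
            output_dir=raw.get("output_dir"),
            make_figures=bool(raw.get("make_figures", False)),
            reproduce=bool(raw.get("reproduce", False)),
            tolerance_factor=float(raw.get("tolerance_factor", 1.5)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    table: CompoundTable
    models: dict[str, MlrModel]
    validations: dict[str, ValidationReport]
    ad_reports: dict[str, AdReport]
    failures: dict[str, str]
    model_frame: pd.DataFrame             # one row per model, global stats
    validation_frame: pd.DataFrame
    comparison: pd.DataFrame | None       # reproduce mode only
    all_reproduced: bool | None
    summary: dict


def _load_table(config: RunConfig) -> CompoundTable:
    if config.compound_path is None:
        return load_bundled_dataset()
    return read_compound_table(config.compound_path, retention_path=config.retention_path)


def _prepare_descriptors(table: CompoundTable, cmc: float) -> dict[str, str]:
    """Fit Foley models and derive log_k01; return per-compound failures."""
    batch = fit_foley_batch(table, cmc)
    log_k01 = {}
    for cid in table.compound_ids:
        series = table.get_series(cid, "MLC")
        if series is None:
            continue
        at01 = np.isclose(series.x, 0.1)
        if at01.any():
            log_k01[cid] = float(np.log10(series.k[at01][0]))
    if log_k01:
        table.set_derived("log_k01", log_k01)
    return batch.failures


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run retention fitting, all model fits, validation and AD analysis."""
    table = _load_table(config)
    failures: dict[str, str] = {}
    foley_failures = _prepare_descriptors(table, config.cmc)
    for cid, msg in foley_failures.items():
        failures[f"foley:{cid}"] = msg

    models: dict[str, MlrModel] = {}
    validations: dict[str, ValidationReport] = {}
    ad_reports: dict[str, AdReport] = {}
    model_rows = {}
    val_rows = {}
    for spec in config.model_specs:
        label = spec.label or spec.formula()
        try:
            model = fit_mlr(table, spec)
            validation = loo_validate(model, table)
        except ChromQsarError as exc:
            logger.warning("model %s failed: %s", label, exc)
            failures[label] = str(exc)
            continue
        try:
            ad = williams_data(model)
        except ChromQsarError as exc:
            # e.g. a zero-residual fit: the model itself is kept
            logger.warning("AD analysis for %s failed: %s", label, exc)
            failures[f"ad:{label}"] = str(exc)
            ad = None
        models[label] = model
        validations[label] = validation
        if ad is not None:
            ad_reports[label] = ad
        model_rows[label] = {
            "formula": model.coefficient_string(),
            "n": model.n,
            "r_squared": model.r_squared,
            "sd": model.sd_resid,
            "f": model.f_stat,
            "p_value": model.p_value,
            "max_vif": float(validation.vif.max()),
        }
        val_rows[label] = {
            "adj_r_squared": model.adj_r_squared,
            "press": validation.press,
            "mse_resid": validation.mse_resid,
            "q_squared": validation.q_squared,
            "mse_cv": validation.mse_cv,
            "n_leverage_outliers": len(ad.leverage_outliers) if ad else np.nan,
            "n_residual_outliers": len(ad.residual_outliers) if ad else np.nan,
        }
        logger.debug("fitted %s: %s", label, model_rows[label])

    model_frame = pd.DataFrame.from_dict(model_rows, orient="index")
    model_frame.index.name = "label"
    validation_frame = pd.DataFrame.from_dict(val_rows, orient="index")
    validation_frame.index.name = "label"

    comparison = None
    all_ok = None
    if config.reproduce:
        comparison = reproduce_reference(table, models, validations, config.tolerance_factor)
        all_ok = bool(comparison["passed"].all())

    summary = _build_summary(models, validations, ad_reports, failures, comparison)
    if config.output_dir is not None:
        _write_outputs(config, table, models, validations, ad_reports,
                       model_frame, validation_frame, comparison, summary)
    return PipelineResult(
        table=table,
        models=models,
        validations=validations,
        ad_reports=ad_reports,
        failures=failures,
        model_frame=model_frame,
        validation_frame=validation_frame,
        comparison=comparison,
        all_reproduced=all_ok,
        summary=summary,
    )


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _build_summary(models, validations, ad_reports, failures, comparison) -> dict:
    summary = {"models": {}, "failures": dict(sorted(failures.items()))}
    for label in sorted(models, key=_label_key):
        m = models[label]
        v = validations[label]
        ad = ad_reports.get(label)
        summary["models"][label] = {
            "response": m.spec.response,
            "predictors": list(m.spec.predictors),
            "n": m.n,
            "coefficients": {k: float(m.params[k]) for k in m.params.index},
            "standard_errors": {k: float(m.bse[k]) for k in m.bse.index},
            "r_squared": m.r_squared,
            "adj_r_squared": m.adj_r_squared,
            "sd": m.sd_resid,
            "f": m.f_stat,
            "p_value": m.p_value,
            "press": v.press,
            "q_squared": v.q_squared,
            "max_vif": float(v.vif.max()),
            "h_star": ad.h_star if ad else None,
            "leverage_outliers": ad.leverage_outliers if ad else None,
            "residual_outliers": ad.residual_outliers if ad else None,
        }
    if comparison is not None:
        summary["reproduction"] = {
            "n_cells": int(len(comparison)),
            "n_passed": int(comparison["passed"].sum()),
            "all_passed": bool(comparison["passed"].all()),
        }
    return _round_floats(summary)


def _label_key(label: str):
    return (0, int(label[2:])) if label.startswith("Eq") and label[2:].isdigit() else (1, label)


def _write_outputs(config, table, models, validations, ad_reports,
                   model_frame, validation_frame, comparison, summary) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_frame.to_csv(out / "models.csv")
    validation_frame.to_csv(out / "validation.csv")
    for label, ad in ad_reports.items():
        ad.frame().to_csv(out / f"ad_{label}.csv")
    if comparison is not None:
        comparison.to_csv(out / "reproduction.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if config.make_figures:
        from . import plots

        for label, model in models.items():
            plots.predicted_vs_actual(model, path=out / f"pred_vs_actual_{label}.png")
            plots.standardized_coefficient_bars(
                model, table, path=out / f"std_coefficients_{label}.png"
            )
            plots.williams_plot(ad_reports[label], path=out / f"williams_{label}.png")


def _compare(rows, label, quantity, computed, printed_str, factor, tol=None):
    printed = printed_value(printed_str)
    if tol is None:
        tol = printed_tolerance(printed_str, factor)
    rows.append({
        "label": label,
        "quantity": quantity,
        "computed": computed,
        "printed": printed,
        "tolerance": tol,
        "passed": bool(abs(computed - printed) <= tol),
    })


def reproduce_reference(
    table: CompoundTable,
    models: dict[str, MlrModel],
    validations: dict[str, ValidationReport],
    factor: float = 1.5,
) -> pd.DataFrame:
    """Cell-by-cell comparison of refitted statistics with the published values.

    Returns a tidy frame (label, quantity, computed, printed, tolerance,
    passed). F statistics are compared after rounding to the printed
    integer; the max-VIF bound is checked one-sidedly.
    """
    rows: list[dict] = []
    log_km = table.derived_descriptors.get("log_km", {})
    from .foley import fit_foley

    for cid, (lkm_str, r2_str) in REFERENCE_FOLEY.items():
        series = table.get_series(cid, "MLC")
        if series is None or cid not in log_km:
            continue
        fit = fit_foley(series)
        _compare(rows, f"foley:{cid}", "log_km", fit.log_km, lkm_str, factor,
                 tol=FOLEY_LOG_KM_TOL)
        _compare(rows, f"foley:{cid}", "r_squared", fit.r_squared, r2_str, factor,
                 tol=FOLEY_R2_TOL)
    for label, ref in REFERENCE_MODELS.items():
        if label not in models:
            continue
        m = models[label]
        v = validations[label]
        for j, (est_str, se_str) in enumerate(ref["coefficients"]):
            _compare(rows, label, f"coef[{j}]", float(m.params.iloc[j]), est_str, factor)
            _compare(rows, label, f"se[{j}]", float(m.bse.iloc[j]), se_str, factor)
        _compare(rows, label, "r_squared", m.r_squared, ref["r_squared"], factor)
        _compare(rows, label, "sd", m.sd_resid, ref["sd"], factor)
        _compare(rows, label, "f", float(round(m.f_stat)), ref["f"], factor)
        _compare(rows, label, "adj_r_squared", m.adj_r_squared, ref["adj_r_squared"], factor)
        _compare(rows, label, "press", v.press, ref["press"], factor)
        vif_bound = printed_value(ref["vif_max"])
        vif_tol = printed_tolerance(ref["vif_max"], factor)
        rows.append({
            "label": label, "quantity": "max_vif",
            "computed": float(v.vif.max()), "printed": vif_bound,
            "tolerance": vif_tol,
            "passed": bool(v.vif.max() < vif_bound + vif_tol),
        })
    return pd.DataFrame(rows)


def eluent_correlation_report(table: CompoundTable) -> pd.DataFrame:
    """Pairwise Pearson correlations of log10 k across micellar eluents.

    Each micellar eluent concentration gives one log k vector over the
    compounds; the matrix of their pairwise correlations quantifies how
    interchangeable retention at the different surfactant levels is as a
    lipophilicity measure.
    """
    vectors: dict[str, dict[float, float]] = {}
    for cid in table.compound_ids:
        series = table.get_series(cid, "MLC")
        if series is None:
            raise DataValidationError(f"compound {cid} has no MLC series")
        vectors[cid] = dict(zip(series.x, np.log10(series.k)))
    grids = {tuple(sorted(v)) for v in vectors.values()}
    if len(grids) != 1:
        raise DataValidationError(
            f"compounds measured on different concentration grids: {sorted(grids)}"
        )
    grid = sorted(grids.pop())
    data = pd.DataFrame(
        {x: [vectors[cid][x] for cid in table.compound_ids] for x in grid},
        index=table.compound_ids,
    )
    corr = data.corr(method="pearson")
    corr.index.name = corr.columns.name = "surfactant_molarity"
    return corr
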