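"""Static figures: predicted-vs-actual, standardized coefficients, Williams plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .domain import AdReport
from .mlr import MlrModel, standardized_coefficients


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def predicted_vs_actual(model: MlrModel, path: str | Path | None = None):
    """Scatter of model predictions against the observed response, with identity line."""
    fig, ax = plt.subplots(figsize=(4, 4))
    y, yhat = model.y, model.fitted
    ax.scatter(y, yhat, s=25, edgecolor="k", linewidth=0.5, zorder=3)
    lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
    pad = 0.05 * (lims[1] - lims[0] or 1.0)
    lims = [lims[0] - pad, lims[1] + pad]
    ax.plot(lims, lims, "k--", linewidth=1)
    ax.set_xlim(lims), ax.set_ylim(lims)
    ax.set_xlabel(f"actual {model.spec.response}")
    ax.set_ylabel(f"predicted {model.spec.response}")
    ax.set_title(f"{model.spec.label or model.spec.formula()}  R$^2$={model.r_squared:.3f}")
    return _finish(fig, path)


def standardized_coefficient_bars(model: MlrModel, table=None, path: str | Path | None = None):
    """Horizontal bars of standardized betas (sign = direction of effect)."""
    betas = standardized_coefficients(model)
    fig, ax = plt.subplots(figsize=(4.5, 0.6 * len(betas) + 1.2))
    colors = ["#2166ac" if b >= 0 else "#b2182b" for b in betas]
    ax.barh(list(betas.index), betas.values, color=colors, edgecolor="k", linewidth=0.5)
    ax.axvline(0, color="k", linewidth=1)
    ax.set_xlabel("standardized coefficient")
    ax.set_title(model.spec.label or model.spec.formula())
    return _finish(fig, path)


def williams_plot(ad: AdReport, path: str | Path | None = None):
    """Standardized residual vs leverage with h* and +/- residual cutoffs."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(ad.leverages, ad.std_residuals, s=25, edgecolor="k", linewidth=0.5, zorder=3)
    ax.axvline(ad.h_star, color="r", linestyle="--", linewidth=1, label=f"h* = {ad.h_star:.3f}")
    for yline in (-ad.residual_cutoff, ad.residual_cutoff):
        ax.axhline(yline, color="gray", linestyle=":", linewidth=1)
    ymax = max(ad.residual_cutoff + 0.5, float(np.abs(ad.std_residuals).max()) + 0.5)
    ax.set_ylim(-ymax, ymax)
    ax.set_xlim(0, max(ad.h_star * 1.2, float(ad.leverages.max()) * 1.1))
    ax.set_xlabel("leverage $h_{ii}$")
    ax.set_ylabel("standardized residual")
    ax.set_title(ad.label)
    ax.legend(loc="upper right", fontsize=8)
    return _finish(fig, path)
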