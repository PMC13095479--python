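"""Control plots, model-comparison plots and the cross-solver outlier check.

A control plot shows, for one curve and one fitted model, the measured
quantum yields (triangles), the computed ETR values (dots) and the model
regression on a dense PAR grid, with the standardized parameter table
underneath (NA printed as "NA").  The combined plot overlays all fitted
models with a per-model goodness table.  Plots default to PDF; PNG follows
from the file extension.

``flag_outliers`` implements the 3%-relative-difference rule used to
compare parameter estimates from an external solver against this package's:
the relative difference is measured against this package's value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import light_models as lm

__all__ = ["OutlierFlag", "plot_control", "combo_plot", "flag_outliers"]

DEFAULT_OUTLIER_THRESHOLD = 0.03


@dataclass(frozen=True)
class OutlierFlag:
    """Cross-solver agreement for one parameter.

    ``rel_diff = |value_a - value_b| / |value_b|`` (``value_b`` is this
    package's estimate); ``is_outlier`` iff the relative difference exceeds
    the threshold.  ``note`` marks parameters skipped because one side is
    NA or the reference is zero.
    """

    name: str
    value_a: Optional[float]
    value_b: Optional[float]
    rel_diff: Optional[float]
    is_outlier: bool
    note: str = ""


def flag_outliers(params_a: dict, params_b: dict,
                  threshold: float = DEFAULT_OUTLIER_THRESHOLD) -> list:
    """Flag parameters whose relative difference exceeds ``threshold``.

    ``params_a`` holds the external solver's values, ``params_b`` this
    package's; only names present in both are compared.  NA (None/NaN)
    values are skipped with a note rather than flagged.
    """
    shared = [k for k in params_a if k in params_b]
    if not shared:
        raise ValueError("no shared parameter names to compare")
    flags = []
    for name in shared:
        a, b = params_a[name], params_b[name]
        a_na = a is None or (isinstance(a, float) and np.isnan(a))
        b_na = b is None or (isinstance(b, float) and np.isnan(b))
        if a_na or b_na:
            flags.append(OutlierFlag(name, a, b, None, False, note="skipped: NA value"))
            continue
        if b == 0:
            if a == 0:
                flags.append(OutlierFlag(name, a, b, 0.0, False))
            else:
                flags.append(OutlierFlag(name, a, b, None, False,
                                         note="skipped: reference value is zero"))
            continue
        rel = abs(a - b) / abs(b)
        flags.append(OutlierFlag(name, a, b, rel, rel > threshold))
    return flags


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def _param_table_rows(fit) -> list:
    rows = [("model", fit.model),
            ("residual_sum_of_squares", f"{fit.metrics.rss:.6g}"),
            ("root_mean_squared_error", f"{fit.metrics.rmse:.6g}"),
            ("relative_root_mean_squared_error",
             "NA" if fit.metrics.rrmse is None else f"{fit.metrics.rrmse:.6g}")]
    for name, val in fit.derived.as_dict().items():
        rows.append((name, "NA" if val is None else f"{val:.6g}"))
    return rows


def _draw_table(ax, rows) -> None:
    ax.axis("off")
    table = ax.table(cellText=[(n, v) for n, v in rows],
                     colLabels=("parameter", "value"),
                     loc="center", cellLoc="left")
    table.auto_set_font_size(False)
    table.set_fontsize(7)
    table.scale(1.0, 1.1)


def plot_control(curve, fit, path) -> str:
    """Write a one-page control plot for a converged fit; returns ``path``."""
    if not fit.converged:
        raise ValueError("control plot requires a converged fit")
    fig, (ax, ax_tab) = plt.subplots(
        2, 1, figsize=(7, 9), gridspec_kw={"height_ratios": (2, 1.6)})
    par = curve.par
    grid = np.linspace(0.0, float(par.max()), 400)
    ax.plot(par, curve.etr, "o", color="black", label="ETR")
    ax.plot(grid, np.asarray(lm.predict(fit.model, fit.raw_params, grid)),
            "-", color="tab:blue", label=f"{fit.model} regression")
    ax.set_xlabel("PAR (umol photons m$^{-2}$ s$^{-1}$)")
    ax.set_ylabel("ETR (umol electrons m$^{-2}$ s$^{-1}$)")
    ax2 = ax.twinx()
    ax2.plot(par, curve.quantum_yield, "^", color="black", markerfacecolor="none",
             label=f"Y({curve.etr_type})")
    ax2.set_ylabel(f"Y({curve.etr_type})")
    ax2.set_ylim(0, 1)
    h1, l1 = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(h1 + h2, l1 + l2, loc="lower right", fontsize=8)
    ax.set_title(curve.source_file, fontsize=9)
    _draw_table(ax_tab, _param_table_rows(fit))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def combo_plot(curve, fits, path) -> str:
    """Overlay every converged fit on the observed curve; returns ``path``."""
    converged = [f for f in fits if f is not None and f.converged]
    if not converged:
        raise ValueError("combined plot requires at least one converged fit")
    fig, (ax, ax_tab) = plt.subplots(
        2, 1, figsize=(7, 9), gridspec_kw={"height_ratios": (2, 1)})
    par = curve.par
    grid = np.linspace(0.0, float(par.max()), 400)
    ax.plot(par, curve.etr, "o", color="black", label="ETR")
    for fit in converged:
        ax.plot(grid, np.asarray(lm.predict(fit.model, fit.raw_params, grid)),
                "-", label=fit.model)
    ax.set_xlabel("PAR (umol photons m$^{-2}$ s$^{-1}$)")
    ax.set_ylabel("ETR (umol electrons m$^{-2}$ s$^{-1}$)")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_title(curve.source_file, fontsize=9)
    rows = [(f.model,
             f"rss={f.metrics.rss:.6g}  rmse={f.metrics.rmse:.6g}  "
             + ("rrmse=NA" if f.metrics.rrmse is None
                else f"rrmse={f.metrics.rrmse:.6g}"))
            for f in converged]
    _draw_table(ax_tab, rows)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)
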