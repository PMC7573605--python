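"""Figures: Bland-Altman, scatter-with-regression, and four-quadrant plots.

All functions take an ``ax`` and return it, so figures compose; phase colours
follow the convention blue = pre-bleeding, red = bleeding, green =
post-bleeding.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .data_model import Dataset, PHASES, UNITS
from .agreement import AgreementResult
from .trending import ChangePair, TrendingResult

__all__ = ["bland_altman_plot", "regression_plot", "four_quadrant_plot", "PHASE_COLORS"]

PHASE_COLORS = {"pre_bleeding": "tab:blue", "bleeding": "tab:red",
                "post_bleeding": "tab:green"}


def _scatter_by_phase(ax, dataset: Dataset, variable: str, x_of, y_of):
    for phase in PHASES:
        sub = dataset.select(variable=variable, phase=phase)
        if sub.empty:
            continue
        ref = sub["reference_value"].to_numpy()
        dev = sub["device_value"].to_numpy()
        ax.scatter(x_of(ref, dev), y_of(ref, dev), s=14, alpha=0.7,
                   color=PHASE_COLORS[phase], label=phase.replace("_", "-"))


def bland_altman_plot(dataset: Dataset, result: AgreementResult, ax=None):
    """Difference-vs-mean plot with bias and limits of agreement."""
    if ax is None:
        _, ax = plt.subplots()
    _scatter_by_phase(ax, dataset, result.variable,
                      lambda r, d: (r + d) / 2.0, lambda r, d: d - r)
    ax.axhline(result.bias, color="k", lw=1.2)
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    unit = UNITS[result.variable]
    ax.set_xlabel(f"mean of methods ({unit})")
    ax.set_ylabel(f"device - reference ({unit})")
    ax.set_title(
        f"{result.variable}: bias {result.bias:.2f}, "
        f"LOA ({result.loa_lower:.2f}, {result.loa_upper:.2f})")
    ax.legend(fontsize=8)
    return ax


def regression_plot(dataset: Dataset, result: AgreementResult, ax=None):
    """Device vs reference scatter with identity and regression lines."""
    if ax is None:
        _, ax = plt.subplots()
    _scatter_by_phase(ax, dataset, result.variable,
                      lambda r, d: r, lambda r, d: d)
    sub = dataset.select(variable=result.variable)
    lo = min(sub["reference_value"].min(), sub["device_value"].min())
    hi = max(sub["reference_value"].max(), sub["device_value"].max())
    xs = np.linspace(lo, hi, 2)
    ax.plot(xs, xs, "k--", lw=1.0, label="identity")
    ax.plot(xs, result.intercept + result.slope * xs, "k-", lw=1.2,
            label=f"fit (r={result.pearson_r:.2f})")
    unit = UNITS[result.variable]
    ax.set_xlabel(f"reference ({unit})")
    ax.set_ylabel(f"device ({unit})")
    ax.set_title(f"{result.variable}")
    ax.legend(fontsize=8)
    return ax


def four_quadrant_plot(changes: list[ChangePair], result: TrendingResult, ax=None):
    """Successive device changes vs reference changes with the exclusion square."""
    if ax is None:
        _, ax = plt.subplots()
    d_ref = np.array([p.d_ref for p in changes])
    d_dev = np.array([p.d_dev for p in changes])
    excl = np.array([p.excluded for p in changes])
    ax.scatter(d_ref[~excl], d_dev[~excl], s=14, alpha=0.7, color="tab:blue",
               label="retained")
    if excl.any():
        ax.scatter(d_ref[excl], d_dev[excl], s=14, alpha=0.4, color="0.6",
                   label="excluded")
    z = result.zone
    ax.add_patch(plt.Rectangle((-z, -z), 2 * z, 2 * z, fill=False,
                               edgecolor="k", ls="--", lw=1.0))
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    lim = 1.1 * max(np.abs(d_ref).max(), np.abs(d_dev).max(), z)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    unit = UNITS[result.variable]
    ax.set_xlabel(f"reference change ({unit})")
    ax.set_ylabel(f"device change ({unit})")
    rate = (f"{result.concordance_rate:.0f}%"
            if np.isfinite(result.concordance_rate) else "undefined")
    ax.set_title(f"{result.variable}: concordance {rate}")
    ax.legend(fontsize=8)
    return ax
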