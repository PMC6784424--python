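"""Matplotlib renderings of bias detection curves and validation charts."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless batch use; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import BiasDetectionCurve, ValidationChartData

__all__ = ["plot_bias_detection_curves", "plot_validation_chart"]


def _bias_axis(bias_levels: Sequence[float]):
    """Categorical positions for the signed bias grid, negative to positive."""
    levels = sorted(bias_levels)
    return levels, np.arange(len(levels))


def plot_bias_detection_curves(
    curves: Sequence[BiasDetectionCurve],
    title: str = "",
    window: Optional[int] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Figure:
    """Overlay candidate curves: median results-to-detection vs bias size.

    Undetected bias levels are drawn at the top of the axis (at ``window``
    when given) with an open marker, so a procedure's blind spots stay
    visible instead of silently dropping out of the plot.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4.5))
    else:
        fig = ax.figure
    all_levels = sorted({p.bias_percent for c in curves for p in c.points})
    levels, xs = _bias_axis(all_levels)
    pos = {b: x for b, x in zip(levels, xs)}
    ceiling = window if window is not None else max(
        (p.median_n for c in curves for p in c.points if p.median_n is not None),
        default=1.0,
    )
    for curve in curves:
        x = [pos[p.bias_percent] for p in curve.points]
        y = [p.median_n if p.median_n is not None else np.nan for p in curve.points]
        (line,) = ax.plot(x, y, marker="o", ms=4, label=curve.config_id)
        missed = [pos[p.bias_percent] for p in curve.points if p.median_n is None]
        if missed:
            ax.plot(
                missed,
                [ceiling] * len(missed),
                linestyle="none",
                marker="^",
                mfc="none",
                color=line.get_color(),
            )
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{b:g}" for b in levels], rotation=45, fontsize=8)
    ax.set_xlabel("bias (%)")
    ax.set_ylabel("median number of results to detection")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_validation_chart(
    chart: ValidationChartData,
    daily_volume: Optional[int] = None,
    title: str = "",
    ax: Optional[plt.Axes] = None,
) -> plt.Figure:
    """Bars at the median with min/max error bars, one bar per bias size."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4.5))
    else:
        fig = ax.figure
    levels, xs = _bias_axis([r.bias_percent for r in chart.rows])
    by_bias = {r.bias_percent: r for r in chart.rows}
    meds, lo_err, hi_err = [], [], []
    for b in levels:
        r = by_bias[b]
        med = r.median_n if r.median_n is not None else 0.0
        meds.append(med)
        lo_err.append(med - (r.min_n if r.min_n is not None else med))
        hi_err.append((r.max_n if r.max_n is not None else med) - med)
    ax.bar(xs, meds, yerr=[lo_err, hi_err], capsize=3, color="0.6", edgecolor="0.2")
    if daily_volume is not None:
        ax.axhline(daily_volume, color="firebrick", ls="--", lw=1,
                   label=f"daily volume ({daily_volume})")
        ax.legend(fontsize=8)
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{b:g}" for b in levels], rotation=45, fontsize=8)
    ax.set_xlabel("bias (%)")
    ax.set_ylabel("results to detection (median, min–max)")
    ax.set_title(title or chart.config_id)
    fig.tight_layout()
    return fig
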