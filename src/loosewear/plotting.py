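"""Plots for sweep results and the model distributions."""

from __future__ import annotations

import numpy as np

from .distributions import fabric_cdf, fabric_pdf, rigid_cdf, rigid_pdf
from .simulate import RIGID_SENSOR
from .sweeps import aggregate


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_distributions(half_widths=(0.5, 1.0), ax=None):
    """Overlay rigid and fabric PDFs/CDFs for the given half-widths zL."""
    ax = _axes(ax)
    u = np.linspace(-1.001, 1.001, 800)
    ax.plot(u, rigid_cdf(u), label="rigid CDF", lw=2)
    for zl in half_widths:
        y = np.linspace(-1 - zl, 1 + zl, 800)
        ax.plot(y, fabric_cdf(y, zl), label=f"fabric CDF, zL={zl:g}")
    ax.set_xlabel("position (amplitude units)")
    ax.set_ylabel("F")
    ax.legend()
    return ax


def plot_window_sweep(results, ax=None):
    """Mean +/- sd accuracy against window size, one line per sensor."""
    ax = _axes(ax)
    agg = aggregate(results)
    for sensor, grp in agg.groupby("sensor_id"):
        grp = grp.sort_values("window_s")
        style = dict(marker="o")
        if sensor == RIGID_SENSOR:
            style.update(color="k", ls="--")
        ax.errorbar(grp["window_s"], grp["accuracy_mean"],
                    yerr=grp["accuracy_std"].fillna(0.0), label=sensor, **style)
    ax.set_xlabel("window size (s)")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0.45, 1.02)
    ax.legend(title="sensor")
    return ax


def plot_frequency_sweep(results, ax=None):
    """Accuracy and KS distance D against the class-1 frequency."""
    ax = _axes(ax)
    agg = aggregate(results)
    for sensor, grp in agg.groupby("sensor_id"):
        grp = grp.sort_values("omega_high")
        ax.plot(grp["omega_high"], grp["accuracy_mean"], marker="o", label=f"{sensor} acc")
        ax.plot(grp["omega_high"], grp["ks_stat_mean"], marker="x", ls=":",
                label=f"{sensor} D")
    ax.set_xlabel("omega_high (rad/s)")
    ax.set_ylabel("accuracy / KS distance")
    ax.legend(fontsize="small")
    return ax
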