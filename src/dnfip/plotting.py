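"""Figures for run records: output-distribution-over-time panels (linear
and logarithmic color scales), parameter traces, and the windowed
input-output correlation."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.colors import LogNorm

from .metrics import SlidingWindowSpec, io_correlation, sliding_histogram

__all__ = ["plot_histogram_over_time", "plot_parameter_traces", "plot_run_overview"]


def plot_histogram_over_time(
    y, times, spec: SlidingWindowSpec | None = None, log_scale: bool = False, ax=None
):
    """Sliding-window histogram of the output measure as an image:
    time on the horizontal axis, output value on the vertical axis,
    shading = occurrence count in the trailing window."""
    if spec is None:
        spec = SlidingWindowSpec(stride=10.0)
    ev, counts = sliding_histogram(y, times, spec)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    c = counts.T.astype(float)
    norm = LogNorm(vmin=1, vmax=max(c.max(), 2)) if log_scale else None
    ax.imshow(
        np.ma.masked_equal(c, 0) if log_scale else c,
        aspect="auto",
        origin="lower",
        extent=(ev[0] / 60.0, ev[-1] / 60.0, 0.0, 1.0),
        cmap="Greys",
        norm=norm,
    )
    ax.set_xlabel("time [min]")
    ax.set_ylabel("output measure y")
    return ax


def plot_parameter_traces(df, ax=None):
    """Gain and bias over time (simulated minutes)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t_min = df["t"].to_numpy() / 60.0
    ax.plot(t_min, df["a"], label="gain a")
    ax.plot(t_min, df["b"], label="bias b")
    ax.set_xlabel("time [min]")
    ax.legend(loc="best")
    return ax


def plot_run_overview(df, window: float = 300.0, path=None):
    """Four-panel overview of a run: histogram over time (linear + log),
    parameter traces, and the windowed input-output correlation."""
    y = df["y"].to_numpy()
    z = df["z"].to_numpy()
    t = df["t"].to_numpy()
    fig, axes = plt.subplots(4, 1, figsize=(9, 10), sharex=True)
    spec = SlidingWindowSpec(window=window, stride=10.0)
    plot_histogram_over_time(y, t, spec, log_scale=False, ax=axes[0])
    axes[0].set_title("output distribution (sliding window)")
    plot_histogram_over_time(y, t, spec, log_scale=True, ax=axes[1])
    axes[1].set_title("log color scale")
    plot_parameter_traces(df, ax=axes[2])
    ev, corr = io_correlation(z, y, t, spec)
    axes[3].plot(ev / 60.0, corr)
    axes[3].set_ylabel("corr(z, y)")
    axes[3].set_xlabel("time [min]")
    axes[3].set_ylim(-1.05, 1.05)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
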