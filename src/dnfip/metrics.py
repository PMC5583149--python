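"""Evaluation statistics over run traces.

Sliding-window output histograms (the distribution-over-time panels),
the windowed Pearson correlation between the input measure z and the
output measure y, and a convergence monitor for the adapted parameters.
Windows are trailing and half-open, ``(t - window, t]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlidingWindowSpec",
    "sliding_histogram",
    "io_correlation",
    "sliding_mean",
    "convergence_monitor",
]


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Trailing-window layout: length and stride in seconds, histogram
    bins over [0, 1].  The 300 s default covers one full input period."""

    window: float = 300.0
    n_bins: int = 50
    stride: float | None = None  # default: the series' own sampling step

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.stride is not None and self.stride <= 0:
            raise ValueError("stride must be positive")


def _eval_times(times: np.ndarray, spec: SlidingWindowSpec) -> np.ndarray:
    stride = spec.stride
    if stride is None:
        return times
    return np.arange(times[0], times[-1] + 0.5 * stride, stride)


def _window_bounds(times: np.ndarray, eval_times: np.ndarray, window: float):
    left = np.searchsorted(times, eval_times - window, side="right")
    right = np.searchsorted(times, eval_times, side="right")
    return left, right


def sliding_histogram(
    y_series: np.ndarray, times: np.ndarray, spec: SlidingWindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of y within each trailing window.

    Returns ``(eval_times, counts)`` with ``counts[k]`` the per-bin counts
    (bins equally spaced over [0, 1]) of the samples in
    ``(eval_times[k] - window, eval_times[k]]``.  Counts sum to the
    number of samples in the window; an empty window gives zero counts.
    """
    y = np.asarray(y_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if y.shape != times.shape:
        raise ValueError("series and times must be aligned")
    edges = np.linspace(0.0, 1.0, spec.n_bins + 1)
    idx = np.clip(np.digitize(y, edges) - 1, 0, spec.n_bins - 1)
    ev = _eval_times(times, spec)
    left, right = _window_bounds(times, ev, spec.window)
    counts = np.zeros((ev.size, spec.n_bins), dtype=np.int64)
    cur = np.zeros(spec.n_bins, dtype=np.int64)
    lp = rp = 0
    for k in range(ev.size):
        l, r = left[k], right[k]
        if r > rp:
            cur += np.bincount(idx[rp:r], minlength=spec.n_bins)
        if l > lp:
            cur -= np.bincount(idx[lp:l], minlength=spec.n_bins)
        lp, rp = l, r
        counts[k] = cur
    return ev, counts


def io_correlation(
    z_series: np.ndarray,
    y_series: np.ndarray,
    times: np.ndarray,
    spec: SlidingWindowSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of (z, y) within each trailing window.

    Windows with fewer than two samples or with zero variance in either
    series yield NaN (a missing value, never a silent 0).
    """
    z = np.asarray(z_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (z.shape == y.shape == times.shape):
        raise ValueError("series and times must be aligned")
    ev = _eval_times(times, spec)
    left, right = _window_bounds(times, ev, spec.window)
    # prefix sums for O(1) window moments
    cz = np.concatenate([[0.0], np.cumsum(z)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    czz = np.concatenate([[0.0], np.cumsum(z * z)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    czy = np.concatenate([[0.0], np.cumsum(z * y)])
    n = (right - left).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sz = cz[right] - cz[left]
        sy = cy[right] - cy[left]
        var_z = (czz[right] - czz[left]) - sz * sz / n
        var_y = (cyy[right] - cyy[left]) - sy * sy / n
        cov = (czy[right] - czy[left]) - sz * sy / n
        corr = cov / np.sqrt(var_z * var_y)
    # numerical guard: cancellation can leave tiny negative variances
    bad = (n < 2) | (var_z <= 1e-12 * n) | (var_y <= 1e-12 * n)
    corr = np.where(bad, np.nan, np.clip(corr, -1.0, 1.0))
    return ev, corr


def sliding_mean(
    series: np.ndarray, times: np.ndarray, window: float
) -> np.ndarray:
    """Trailing-window mean of a series, evaluated at every sample time.
    Windows shorter than the nominal length (run start) average what is
    there."""
    x = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    left = np.searchsorted(times, times - window, side="right")
    right = np.arange(1, x.size + 1)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    n = right - left
    return (cx[right] - cx[left]) / n


def convergence_monitor(
    param_series: np.ndarray,
    times: np.ndarray,
    tolerance: float = 0.02,
    horizon: float = 300.0,
    relative: bool = True,
) -> tuple[bool, float | None]:
    """Detect convergence of one or more parameter traces.

    Declares convergence at the earliest time after which every trace
    stays within ``+-tolerance`` of its trailing-``horizon`` mean for a
    full further horizon.  ``tolerance`` is relative to the magnitude of
    the trailing mean by default (2%), or absolute with
    ``relative=False``.  Returns ``(converged, time)``; ``time`` is None
    when the criterion is never met.
    """
    x = np.asarray(param_series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    times = np.asarray(times, dtype=float)
    if times.size != x.shape[0]:
        raise ValueError("series and times must be aligned")
    if horizon > times[-1] - times[0]:
        raise ValueError("horizon exceeds the series span")
    ok = np.ones(times.size, dtype=bool)
    for j in range(x.shape[1]):
        m = sliding_mean(x[:, j], times, horizon)
        tol = tolerance * np.abs(m) if relative else tolerance
        ok &= np.abs(x[:, j] - m) <= tol
    # earliest t0 (with a full trailing window behind it) such that ok
    # holds on [t0, t0 + horizon]
    admissible = times >= times[0] + horizon
    end = np.searchsorted(times, times + horizon, side="right")
    # ok on [i, end_i) for all traces: use prefix sums of ~ok
    bad = np.concatenate([[0], np.cumsum(~ok)])
    for i in np.nonzero(admissible)[0]:
        e = end[i]
        if e > times.size:
            e = times.size
        if times[e - 1] - times[i] + 1e-12 < horizon:
            break  # not enough future left to certify
        if bad[e] - bad[i] == 0:
            return True, float(times[i])
    return False, None
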