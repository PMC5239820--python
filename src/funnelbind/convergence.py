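"""Convergence monitoring of the binding free energy estimate.

The metadynamics estimate dG_meta(t) is re-evaluated on a schedule by
running the full reconstruct -> project -> reference -> standard-state
pipeline on the hills deposited up to each time.  The final value is the
average over the last window W, with the statistical uncertainty taken as
the maximum of two numbers: the fluctuation (standard deviation) of the
estimate inside that window, and the absolute difference between the means
of the two last consecutive W-blocks (which captures residual drift).

The statistical-inefficiency estimator used to thin correlated series for
FEP also lives here: g = 1 + 2 sum_t (1 - t/N) rho(t), with the empirical
autocorrelation summed up to its first non-positive value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvergenceReport",
    "basin_delta_f_timeseries",
    "dg_meta_timeseries",
    "final_estimate",
    "statistical_inefficiency",
]


@dataclass
class ConvergenceReport:
    """Time-resolved dG_meta estimates plus window/block statistics."""

    times: np.ndarray       # evaluation times, ps
    dg_meta: np.ndarray     # kcal/mol
    window: float           # averaging window W, ps
    mean: float
    window_std: float
    block_means: tuple[float, float]
    error: float            # max(window_std, |block mean difference|)


def dg_meta_timeseries(hills, cfg=None, eval_stride: float | None = None,
                       grid=None, cutoff: float | None = 6.0,
                       t_start: float | None = None,
                       t_end: float | None = None):
    """Evaluate dG_meta from the hills deposited up to each time on a
    uniform schedule.

    Returns ``(times, values)``.  Each value runs the full pipeline
    (reconstruct, project, reference, standard-state integral) on the hills
    with deposition time <= t; the bias grid is accumulated incrementally so
    the cost is a single pass over the hills.
    """
    from .binding import BindingConfig, delta_g_meta
    from .fes import GridSpec, _bias_to_fes, _sum_hills_grid, \
        project_pmf, set_reference_level
    from .bias import HillsRecord

    if cfg is None:
        cfg = BindingConfig()
    if grid is None:
        grid = GridSpec()
    if len(hills) == 0:
        raise ValueError("empty hills record")
    t_total = float(hills.times[-1]) if t_end is None else t_end
    t0 = float(hills.times[0]) if t_start is None else t_start
    if eval_stride is None:
        eval_stride = (t_total - t0) / 40.0
    if eval_stride <= 0 or t0 + 2 * eval_stride > t_total:
        raise ValueError("hills record must span at least two eval strides")
    t_evals = np.arange(t0 + eval_stride, t_total + 0.5 * eval_stride,
                        eval_stride)
    ax1, ax2 = grid.axes()
    V = np.zeros((ax1.size, ax2.size))
    mask = np.zeros((ax1.size, ax2.size), dtype=bool)
    values = np.empty(t_evals.size)
    prev_t = -np.inf
    for i, t in enumerate(t_evals):
        sel = (hills.times > prev_t) & (hills.times <= t)
        if np.any(sel):
            sub = HillsRecord(hills.times[sel], hills.centers[sel],
                              hills.widths[sel], hills.heights[sel],
                              hills.gamma)
            try:
                V += _sum_hills_grid(sub, ax1, ax2, t, cutoff, mask)
            except ValueError as exc:
                raise ValueError(f"at t = {t:g} ps: {exc}") from exc
        prev_t = t
        fes = _bias_to_fes(V.copy(), hills.gamma, cfg.T, (0.0, t), ax1, ax2,
                           mask)
        try:
            pmf = set_reference_level(project_pmf(fes), cfg.ref_range)
            values[i] = delta_g_meta(pmf, cfg)
        except ValueError as exc:
            raise ValueError(f"at t = {t:g} ps: {exc}") from exc
    return t_evals, values


def basin_delta_f_timeseries(hills, divider: float = 1.0, lo: float = 0.1,
                             hi: float = 1.9, eval_stride: float = 200.0,
                             t_start: float = 0.0, grid=None,
                             cutoff: float | None = 6.0, T: float = 298.0):
    """Basin free-energy difference from the reconstructed PMF as a
    function of simulation time.

    The double-well analogue of the dG_meta convergence series: at each
    evaluation time the hills deposited so far are reconstructed, projected
    to w(z), and reduced to -kB T ln(Z_left / Z_right) with the basin split
    at ``divider``.  Returns ``(times, values)``.
    """
    from .fes import GridSpec, _bias_to_fes, _sum_hills_grid, \
        pmf_basin_delta_f, project_pmf
    from .bias import HillsRecord

    if grid is None:
        grid = GridSpec()
    if len(hills) == 0:
        raise ValueError("empty hills record")
    ax1, ax2 = grid.axes()
    t_evals = np.arange(t_start, float(hills.times[-1]) + 1e-9, eval_stride)
    V = np.zeros((ax1.size, ax2.size))
    mask = np.zeros((ax1.size, ax2.size), dtype=bool)
    values = np.empty(t_evals.size)
    prev_t = -np.inf
    for i, t in enumerate(t_evals):
        sel = (hills.times > prev_t) & (hills.times <= t)
        if np.any(sel):
            sub = HillsRecord(hills.times[sel], hills.centers[sel],
                              hills.widths[sel], hills.heights[sel],
                              hills.gamma)
            V += _sum_hills_grid(sub, ax1, ax2, t, cutoff, mask)
        prev_t = t
        fes = _bias_to_fes(V.copy(), hills.gamma, T, (0.0, t), ax1, ax2,
                           mask)
        values[i] = pmf_basin_delta_f(project_pmf(fes), divider, lo, hi)
    return t_evals, values


def final_estimate(times, values, window: float) -> ConvergenceReport:
    """Window mean and two-part error estimate of a dG_meta(t) series.

    The mean is taken over the last ``window`` ps.  The error is
    max(std of the values inside the window, |mean of block (-2W, -W] -
    mean of block (-W, 0]|), the second term guarding against slow drift.
    The report is invariant under time translation of the series.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size == 0:
        raise ValueError("times and values must be equal-length, non-empty")
    t_end = times[-1]
    span = t_end - times[0]
    if span < 2 * window - 1e-9:
        raise ValueError(
            f"series spans {span:g} ps, need at least 2 W = {2 * window:g} ps")
    last = times > t_end - window
    prev = (times > t_end - 2 * window) & ~last
    w_mean = float(values[last].mean())
    w_std = float(values[last].std(ddof=0))
    b_prev = float(values[prev].mean())
    err = max(w_std, abs(b_prev - w_mean))
    return ConvergenceReport(times=times, dg_meta=values, window=window,
                             mean=w_mean, window_std=w_std,
                             block_means=(b_prev, w_mean), error=err)


def statistical_inefficiency(series) -> float:
    """Statistical inefficiency g of a time series.

    g = 1 + 2 sum_{t>=1} (1 - t/N) rho(t), with the empirical normalized
    autocorrelation rho summed up to (not including) its first non-positive
    lag; g is floored at 1.  A constant series has no correlation structure
    and returns 1 with a warning.  Invariant under affine transforms of the
    values.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series too short for autocorrelation analysis")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        warnings.warn("constant series: autocorrelation undefined, g = 1")
        return 1.0
    # FFT-based autocovariance at all lags
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / acov[0]
    g = 1.0
    for t in range(1, n):
        if rho[t] <= 0:
            break
        g += 2.0 * (1.0 - t / n) * rho[t]
    return max(g, 1.0)
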