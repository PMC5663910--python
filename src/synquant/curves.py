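"""Curve fitting and time-series processing.

Covers the three model fits used by the assay — the single-site binding
isotherm of the bait/tracer pair (Kd estimation), the mono-exponential
saturation of uptake versus synaptic drive, and the per-bouton uptake
time-series pipeline (ratio normalization, baseline removal, moving
average, time-derivative rate) plus a per-pixel Kalman-style recursive
filter for time-lapse stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "BindingFit",
    "SaturationFit",
    "fit_binding",
    "fit_monoexponential",
    "process_timeseries",
    "kalman_stack_filter",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is degenerate."""


@dataclass
class BindingFit:
    kd: float               # nM
    bmax: float
    hill: float             # 1.0 unless a free Hill slope is requested
    adj_r2: float
    kd_se: float
    bmax_se: float
    residuals: np.ndarray


@dataclass
class SaturationFit:
    amplitude: float
    rate_constant: float
    adj_r2: float
    residuals: np.ndarray


def _adj_r2(y: np.ndarray, resid: np.ndarray, n_params: int) -> float:
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    if ss_tot == 0 or n <= n_params + 1:
        return float("nan")
    r2 = 1 - ss_res / ss_tot
    return 1 - (1 - r2) * (n - 1) / (n - n_params - 1)


def fit_binding(concentrations, responses, free_hill: bool = False) -> BindingFit:
    """Least-squares fit of the saturable binding curve.

    The default model is single-site binding with unit Hill slope,
    y = bmax * c / (c + kd) — the form behind a single reported Kd.  With
    ``free_hill`` the Hill coefficient is fitted too:
    y = bmax * c^h / (c^h + kd^h).

    Initialization: bmax0 = max(y); kd0 = concentration at half-max by
    interpolation.  Parameters are bounded positive.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(c) != len(y):
        raise ValueError("concentrations and responses must align")
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.ptp(y) == 0:
        raise FitError("responses are constant; Kd is unidentifiable")

    bmax0 = float(y.max())
    order = np.argsort(c)
    half = bmax0 / 2
    kd0 = float(np.interp(half, y[order], c[order])) if y.max() > half > y.min() \
        else float(np.median(c))
    kd0 = max(kd0, 1e-9)

    if free_hill:
        def model(c, bmax, kd, h):
            return bmax * c ** h / (c ** h + kd ** h)
        p0, bounds = [bmax0, kd0, 1.0], ([1e-12, 1e-12, 0.1], [np.inf] * 3)
    else:
        def model(c, bmax, kd):
            return bmax * c / (c + kd)
        p0, bounds = [bmax0, kd0], ([1e-12, 1e-12], [np.inf, np.inf])

    try:
        popt, pcov = optimize.curve_fit(model, c, y, p0=p0, bounds=bounds,
                                        maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"binding fit did not converge: {exc}") from exc
    resid = y - model(c, *popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    return BindingFit(
        kd=float(popt[1]), bmax=float(popt[0]),
        hill=float(popt[2]) if free_hill else 1.0,
        adj_r2=_adj_r2(y, resid, len(popt)),
        kd_se=float(se[1]), bmax_se=float(se[0]), residuals=resid,
    )


def fit_monoexponential(x, y) -> SaturationFit:
    """Least-squares fit of y = A * (1 - exp(-k*x)), A, k > 0.

    Describes uptake approaching a ceiling as synaptic drive grows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 points")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")

    a0 = max(float(y.max()), 1e-9)
    pos = (x > 0) & (y > 0) & (y < a0)
    k0 = float(np.median(-np.log1p(-y[pos] / (a0 * 1.0001)) / x[pos])) if pos.any() else 1.0
    k0 = max(k0, 1e-9)

    def model(x, a, k):
        return a * (1 - np.exp(-k * x))

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=[a0, k0],
                                     bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                     maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    return SaturationFit(amplitude=float(popt[0]), rate_constant=float(popt[1]),
                         adj_r2=_adj_r2(y, resid, 2), residuals=resid)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window is truncated at the edges."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(values):
        raise ValueError("window longer than trace")
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def process_timeseries(values, gz_reference: float, frame_interval: float,
                       baseline_frames: int, window: int = 4):
    """Normalize, trim, filter and differentiate one uptake trace.

    The tracer trace is divided by the bouton's reporter fluorescence,
    the initial baseline (frames acquired before tracer wash-in) is
    dropped, a centered 4-sample moving average (window configurable) is
    applied, and the uptake rate is the first difference divided by the
    frame interval.  Returns ``(trace, rate)``; ``rate`` has one sample
    fewer than ``trace``.
    """
    values = np.asarray(values, dtype=float)
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if gz_reference <= 0:
        raise ValueError("gz_reference must be > 0")
    if baseline_frames >= len(values):
        raise ValueError("baseline longer than trace")
    trace = values[baseline_frames:] / gz_reference
    trace = moving_average(trace, window)
    rate = np.diff(trace) / frame_interval
    return trace, rate


def kalman_stack_filter(frames: np.ndarray, gain: float = 0.8,
                        median_size: int = 3) -> np.ndarray:
    """Recursive per-pixel temporal filter for time-lapse stacks.

    Each frame is median-prefiltered spatially, then blended with the
    running estimate: x̂_t = gain * x̂_{t-1} + (1 - gain) * x_t.  The
    first frame passes through (after the median prefilter).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (t>=2, h, w) stack")
    if not 0 <= gain < 1:
        raise ValueError("gain must lie in [0, 1)")
    pre = np.stack([ndimage.median_filter(f, size=median_size) for f in frames])
    out = np.empty_like(pre)
    out[0] = pre[0]
    for t in range(1, len(pre)):
        out[t] = gain * out[t - 1] + (1 - gain) * pre[t]
    return out
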