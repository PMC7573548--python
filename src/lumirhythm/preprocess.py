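"""Signal conditioning for bioluminescence traces.

Two linear, zero-phase filters prepare a raw trace for sinusoid regression:

* **De-trending** subtracts a long (default 24 h) centered running mean,
  removing the slow baseline produced by cell proliferation and reporter
  signal decline while leaving the circadian band essentially intact.
* **Smoothing** replaces the signal by a short (default 2 h) centered running
  mean to suppress shot noise.

Both are discrete boxcar filters.  A boxcar of ``w`` samples at spacing
``dt`` multiplies a sinusoid of period ``T`` by the Dirichlet gain

    G(T) = sin(w·π·dt/T) / (w·sin(π·dt/T)),

the discrete analogue of the continuous ``sinc`` attenuation.  De-trending
therefore passes a sinusoid with gain ``1 − G_detrend(T)`` and smoothing with
gain ``G_smooth(T)``; :func:`preprocess_gain` exposes the combined transfer so
downstream code can undo the known attenuation of a fitted sinusoid.

Edge policy: ``trim`` (default) drops the half-window at each end where the
full centered window does not fit; ``shrink`` keeps full length by using
progressively smaller symmetric windows near the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, TraceLengthError
from .trace import LuminescenceTrace, PlateRecording

STEP_DETREND = "detrend_movavg"
STEP_SMOOTH = "smooth_movavg"


@dataclass(frozen=True)
class PreprocessConfig:
    """Windows (hours) and edge handling for the two conditioning filters."""

    detrend_window_h: float = 24.0
    smooth_window_h: float = 2.0
    edge_policy: str = "trim"

    def __post_init__(self) -> None:
        if self.edge_policy not in ("trim", "shrink"):
            raise ParameterError(
                f"edge_policy must be 'trim' or 'shrink', got "
                f"{self.edge_policy!r}"
            )
        if not self.smooth_window_h > 0:
            raise ParameterError("smooth_window_h must be positive")
        if not self.detrend_window_h > self.smooth_window_h:
            raise ParameterError(
                "detrend_window_h must exceed smooth_window_h"
            )


def window_samples(window_h: float, dt_h: float) -> int:
    """Convert a window length in hours to an odd sample count."""
    w = int(round(window_h / dt_h))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def boxcar_gain(period_h: float, window_h: float, dt_h: float) -> float:
    """Dirichlet gain of the centered odd-sample boxcar at a given period."""
    w = window_samples(window_h, dt_h)
    theta = np.pi * dt_h / period_h
    if w == 1 or theta == 0.0:
        return 1.0
    return float(np.sin(w * theta) / (w * np.sin(theta)))


def preprocess_gain(
    period_h: float, config: PreprocessConfig, dt_h: float
) -> float:
    """Combined gain of detrend followed by smooth for a sinusoid of
    ``period_h`` hours.  Exact for regularly sampled noiseless sinusoids."""
    g_detrend = 1.0 - boxcar_gain(period_h, config.detrend_window_h, dt_h)
    g_smooth = boxcar_gain(period_h, config.smooth_window_h, dt_h)
    return g_detrend * g_smooth


def _require_regular(trace: LuminescenceTrace, op: str) -> None:
    if not trace.is_regular:
        raise ParameterError(f"{op} requires regular sampling "
                             f"(well {trace.well_id!r})")


def _running_mean(y: np.ndarray, w: int, edge_policy: str) -> np.ndarray:
    """Centered running mean; 'trim' returns n-w+1 values, 'shrink' n."""
    if edge_policy == "trim":
        return np.convolve(y, np.ones(w) / w, mode="valid")
    # shrink: symmetric window of half-width min(h, i, n-1-i) at index i
    h = (w - 1) // 2
    n = y.size
    out = np.empty(n)
    for i in range(n):
        m = min(h, i, n - 1 - i)
        out[i] = y[i - m : i + m + 1].mean()
    return out


def detrend_moving_average(
    trace: LuminescenceTrace, config: PreprocessConfig | None = None
) -> LuminescenceTrace:
    """Subtract a long centered running mean to remove baseline drift.

    Requires regular sampling and a duration of at least twice the detrend
    window.  Under ``edge_policy='trim'`` the first and last half-window of
    samples are dropped; ``'shrink'`` keeps the full length.
    """
    config = config or PreprocessConfig()
    _require_regular(trace, "detrend_moving_average")
    if trace.duration_h < 2 * config.detrend_window_h:
        raise TraceLengthError(
            f"detrending needs ≥ {2 * config.detrend_window_h:g} h of data "
            f"(2 × detrend window); well {trace.well_id!r} has "
            f"{trace.duration_h:g} h"
        )
    w = window_samples(config.detrend_window_h, trace.dt_h)
    baseline = _running_mean(trace.signal, w, config.edge_policy)
    if config.edge_policy == "trim":
        h = (w - 1) // 2
        t = trace.time_h[h : trace.n - h]
        y = trace.signal[h : trace.n - h] - baseline
    else:
        t = trace.time_h
        y = trace.signal - baseline
    return trace.with_values(t, y, STEP_DETREND)


def smooth_moving_average(
    trace: LuminescenceTrace, config: PreprocessConfig | None = None
) -> LuminescenceTrace:
    """Centered running-mean denoising over ``smooth_window_h`` hours."""
    config = config or PreprocessConfig()
    _require_regular(trace, "smooth_moving_average")
    w = window_samples(config.smooth_window_h, trace.dt_h)
    if w < 3:
        raise ParameterError(
            f"smooth window of {config.smooth_window_h:g} h is shorter than "
            f"3 samples at dt={trace.dt_h:g} h"
        )
    smoothed = _running_mean(trace.signal, w, config.edge_policy)
    if config.edge_policy == "trim":
        h = (w - 1) // 2
        t = trace.time_h[h : trace.n - h]
    else:
        t = trace.time_h
    return trace.with_values(t, smoothed, STEP_SMOOTH)


def preprocess_trace(
    trace: LuminescenceTrace, config: PreprocessConfig | None = None
) -> LuminescenceTrace:
    """Detrend then smooth — the conditioning applied before fitting."""
    config = config or PreprocessConfig()
    return smooth_moving_average(
        detrend_moving_average(trace, config), config
    )


def average_replicates(
    plate: PlateRecording, condition: str
) -> LuminescenceTrace:
    """Pointwise mean across the wells of one condition.

    Mirrors the display convention of averaging technical repeats; the result
    carries well id ``"<condition>:mean"``.
    """
    wells = plate.wells_for(condition)
    stack = np.vstack([plate.get(w).signal for w in wells])
    steps = plate.get(wells[0]).steps_applied + ("average_replicates",)
    return LuminescenceTrace(
        f"{condition}:mean", plate.time_h, stack.mean(axis=0), steps
    )
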