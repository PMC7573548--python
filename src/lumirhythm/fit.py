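"""Constant-plus-sinusoid regression — the rhythmicity core.

The model is

    y(t) = c + a·sin(2πt/T) + b·cos(2πt/T)

which for a fixed period ``T`` is linear in ``(c, a, b)`` and solved exactly
by ordinary least squares (:func:`fit_fixed_period`).  The period is found by
profiling: a coarse scan of the residual sum of squares over a period grid,
followed by golden-section refinement of the SSE-minimizing bracket
(:func:`fit_sinusoid`).  This two-stage profiled search is globally robust,
deterministic, and trivially checkable against a dense-grid brute force.

Reported quantities:

* ``period_h`` — the oscillation period in hours,
* ``amplitude`` — ``√(a² + b²)``, half the fitted peak-to-trough excursion,
* ``phase_h`` — the time in ``[0, T)`` of the fitted sinusoid's first
  ascending zero-crossing after t = 0,
* ``constant_level`` — the fitted constant ``c``,
* ``r_squared`` — 1 − SSE/SST about the input mean, the rhythmicity score:
  how closely the (conditioned) record follows a sinusoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FitNumericalError, ParameterError, TraceLengthError
from .trace import LuminescenceTrace

#: Total sums of squares below this are treated as a constant signal.
DEGENERATE_SST = 1e-12

#: Coarse-scan SSE ties closer than this resolve to the smaller period.
TIE_TOL = 1e-12

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class FitConfig:
    """Period-search settings: bounds bracket every plausible circadian
    period with margin; the coarse step must resolve distinct SSE minima."""

    period_bounds_h: tuple[float, float] = (16.0, 40.0)
    coarse_step_h: float = 0.05
    refine_tol_h: float = 1e-3

    def __post_init__(self) -> None:
        lo, hi = self.period_bounds_h
        if not lo < hi:
            raise ParameterError("period_bounds_h: lower must be < upper")
        if not 0 < self.coarse_step_h < (hi - lo) / 10:
            raise ParameterError(
                "coarse_step_h must be positive and < (upper-lower)/10"
            )
        if not self.refine_tol_h > 0:
            raise ParameterError("refine_tol_h must be positive")


@dataclass(frozen=True)
class SinusoidFit:
    """Result of the constant-plus-sinusoid regression on one trace."""

    period_h: float
    amplitude: float
    phase_h: float
    constant_level: float
    r_squared: float
    sse: float
    converged: bool
    degenerate: bool


def _design(t: np.ndarray, period_h: float) -> np.ndarray:
    omega = 2.0 * np.pi / period_h
    return np.column_stack(
        (np.ones_like(t), np.sin(omega * t), np.cos(omega * t))
    )


def fit_fixed_period(
    trace: LuminescenceTrace, period_h: float
) -> tuple[float, float, float, float]:
    """Least-squares fit of ``c + a·sin + b·cos`` at a fixed period.

    Returns ``(constant_level, amplitude, phase_h, sse)``.  The phase is the
    time in ``[0, period_h)`` of the fitted sinusoid's first ascending
    zero-crossing after t = 0.

    Raises
    ------
    FitNumericalError
        If the design is rank deficient — e.g. a period so short relative to
        the sampling interval that sine and cosine columns alias.
    """
    if period_h <= 0:
        raise ParameterError(f"period_h must be positive, got {period_h}")
    if trace.n < 4:
        raise TraceLengthError("fit_fixed_period needs at least 4 samples")
    X = _design(trace.time_h, period_h)
    beta, _, rank, _ = np.linalg.lstsq(X, trace.signal, rcond=None)
    if rank < 3:
        raise FitNumericalError(
            f"rank-deficient sinusoid design at period {period_h:g} h "
            f"(dt={trace.dt_h:g} h): sine/cosine columns are aliased"
        )
    c, a, b = (float(v) for v in beta)
    resid = trace.signal - X @ beta
    sse = float(resid @ resid)
    amplitude = math.hypot(a, b)
    # y = c + A·sin(ωt + θ) with θ = atan2(b, a); ascending zeros at
    # ωt + θ = 2πk, i.e. t = (−θ/ω) mod T.
    theta = math.atan2(b, a)
    phase_h = (-theta * period_h / (2.0 * math.pi)) % period_h
    return c, amplitude, phase_h, sse


def _sse_at(trace: LuminescenceTrace, period_h: float) -> float:
    X = _design(trace.time_h, period_h)
    beta, _, rank, _ = np.linalg.lstsq(X, trace.signal, rcond=None)
    if rank < 3:
        return math.inf
    resid = trace.signal - X @ beta
    return float(resid @ resid)


def _golden_section(f, a: float, b: float, tol: float) -> float:
    """Minimize a unimodal f on [a, b] to bracket width ``tol``."""
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def fit_sinusoid(
    trace: LuminescenceTrace, config: FitConfig | None = None
) -> SinusoidFit:
    """Profiled least-squares sinusoid fit with period search.

    Scans the period bounds at ``coarse_step_h``, then refines the best
    bracket by golden-section search on the SSE down to ``refine_tol_h``.
    ``converged`` is True iff the coarse minimum was interior to the bounds.
    An all-constant input yields a degenerate result (``r_squared = 0``,
    ``amplitude = 0``), not an exception.
    """
    config = config or FitConfig()
    lo, hi = config.period_bounds_h
    if trace.duration_h < 2 * lo:
        raise TraceLengthError(
            f"period search down to {lo:g} h needs ≥ {2 * lo:g} h of data; "
            f"trace {trace.well_id!r} has {trace.duration_h:g} h"
        )

    y = trace.signal
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < DEGENERATE_SST:
        return SinusoidFit(
            period_h=lo,
            amplitude=0.0,
            phase_h=0.0,
            constant_level=float(y.mean()),
            r_squared=0.0,
            sse=0.0,
            converged=False,
            degenerate=True,
        )

    grid = np.arange(lo, hi + 0.5 * config.coarse_step_h, config.coarse_step_h)
    grid = grid[grid <= hi + 1e-12]
    sse_grid = np.array([_sse_at(trace, p) for p in grid])
    best = float(sse_grid.min())
    idx = int(np.flatnonzero(sse_grid <= best + TIE_TOL)[0])
    converged = 0 < idx < grid.size - 1

    a = max(lo, grid[idx] - config.coarse_step_h)
    b = min(hi, grid[idx] + config.coarse_step_h)
    period = _golden_section(
        lambda p: _sse_at(trace, p), a, b, config.refine_tol_h
    )

    c, amplitude, phase_h, sse = fit_fixed_period(trace, period)
    r_squared = 1.0 - sse / sst
    return SinusoidFit(
        period_h=float(period),
        amplitude=amplitude,
        phase_h=phase_h,
        constant_level=c,
        r_squared=r_squared,
        sse=sse,
        converged=converged,
        degenerate=False,
    )


def rhythmicity_score(fit: SinusoidFit) -> float:
    """R² clipped to [0, 1] for reporting; 0 for degenerate fits."""
    if fit.degenerate:
        return 0.0
    return float(min(max(fit.r_squared, 0.0), 1.0))
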