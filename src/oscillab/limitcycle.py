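"""Limit-cycle extraction and collective-vs-average frequency comparisons.

Periods are measured on a Poincaré section: upward crossings of the
repressor component through the mean of a trailing window of the
trajectory, with event times refined on the integrator's dense output. The
transient is discarded adaptively — integration proceeds in fixed windows
until two successive period estimates agree to a relative tolerance — so the
quoted period is that of the asymptotic cycle, not of a transient spiral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import NoCycleError, OscillabError, ValidationError
from .models import ModelSystem

__all__ = [
    "CycleSummary",
    "integrate",
    "extract_cycle",
    "frequency_sweep",
    "average_frequency",
    "find_matching_coupling",
]

# the repressor is component x3 (index 2) of the first cell in every model
_SECTION_INDEX = 2


@dataclass(frozen=True)
class CycleSummary:
    """Period, frequency, amplitudes and phase offsets of a detected cycle."""

    period: float
    frequency: float
    amplitude: np.ndarray            # (max - min)/2 per component, final cycle
    phase_differences: np.ndarray | None  # peak-time offset of cell 2 vs cell 1
    convergence: float               # relative change of the last two period estimates
    section_level: float
    cycle_state: np.ndarray          # a point on the cycle (warm start for sweeps)

    @property
    def omega(self) -> float:
        return self.frequency


def integrate(
    model: ModelSystem,
    x0: Sequence[float],
    t_end: float,
    rtol: float = 1e-12,
    atol: float = 1e-14,
    method: str = "DOP853",
    dense_output: bool = True,
    t_eval: Sequence[float] | None = None,
):
    """Adaptive high-order integration of a model from ``x0`` to ``t_end``."""
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.dim,):
        raise ValidationError(f"initial state must have dimension {model.dim}")
    if np.any(x0 < 0):
        raise ValidationError("initial state must be nonnegative")
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    sol = solve_ivp(
        lambda t, x: model.rhs(x),
        (0.0, float(t_end)),
        x0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=dense_output,
        t_eval=t_eval,
    )
    if not sol.success:
        raise OscillabError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    return sol


def _crossing_periods(model, x0, level, horizon, rtol, atol):
    """Upward crossing times of the section component through ``level``."""

    def event(t, x):
        return x[_SECTION_INDEX] - level

    event.direction = 1.0
    sol = solve_ivp(
        lambda t, x: model.rhs(x),
        (0.0, horizon),
        x0,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        events=event,
    )
    return sol.t_events[0], sol.y[:, -1]


def extract_cycle(
    model: ModelSystem,
    x0: Sequence[float] | None = None,
    transient_window: float = 50.0,
    max_time: float = 5000.0,
    rel_tol: float = 1e-9,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> CycleSummary:
    """Integrate past the transient and measure the asymptotic limit cycle.

    Raises :class:`NoCycleError` when the trajectory settles onto the
    equilibrium or the period estimates fail to stabilize within
    ``max_time`` time units.
    """
    if x0 is None:
        eq = model.solve_equilibrium()
        x0 = eq.state * 1.01
    x = np.asarray(x0, dtype=float)

    elapsed = 0.0
    prev_period = None
    prev_span = None
    period = None
    convergence = math.inf
    level = None
    while elapsed < max_time:
        sol = integrate(model, x, transient_window, rtol=rtol, atol=atol)
        x = sol.y[:, -1]
        elapsed += transient_window
        # section level: mean of the window just integrated
        ts = np.linspace(0.0, transient_window, 2001)
        window = sol.sol(ts)
        level = float(window[_SECTION_INDEX].mean())
        span = window[_SECTION_INDEX].max() - window[_SECTION_INDEX].min()
        if span < 1e-9 * (1 + abs(level)):
            raise NoCycleError(
                "trajectory has collapsed onto the equilibrium: no limit cycle"
            )
        # a decaying spiral around a stable focus also has convergent return
        # times, so a cycle is accepted only once the oscillation amplitude
        # has stopped changing between windows as well
        span_stable = prev_span is not None and abs(span / prev_span - 1.0) <= 5e-4
        prev_span = span
        horizon = 6 * (prev_period if prev_period else 2 * math.pi / math.sqrt(3))
        crossings, x = _crossing_periods(model, x, level, horizon, rtol, atol)
        elapsed += horizon
        if len(crossings) < 3:
            continue
        period = float(np.diff(crossings)[-1])
        if prev_period is not None:
            convergence = abs(period - prev_period) / period
            if convergence <= rel_tol and span_stable:
                break
        prev_period = period
    else:
        if period is None:
            raise NoCycleError(
                f"no section crossings within {max_time} time units"
            )
        raise NoCycleError(
            f"period estimates did not stabilize within {max_time} time units "
            f"(last relative change {convergence:.3e})"
        )

    # final full cycle, densely sampled, for amplitudes and phase offsets
    fine = integrate(model, x, period, rtol=rtol, atol=atol)
    ts = np.linspace(0.0, period, 4001)
    orbit = fine.sol(ts)
    amplitude = 0.5 * (orbit.max(axis=1) - orbit.min(axis=1))

    phase_diff = None
    if model.dim == 8:
        phase_diff = np.array(
            [
                _peak_offset(ts, orbit[j], orbit[j + 4], period)
                for j in range(4)
            ]
        )
    return CycleSummary(
        period=period,
        frequency=2 * math.pi / period,
        amplitude=amplitude,
        phase_differences=phase_diff,
        convergence=convergence,
        section_level=level,
        cycle_state=x,
    )


def _peak_offset(ts, comp_a, comp_b, period):
    """Peak-time offset of component b relative to a, folded to [-T/2, T/2)."""
    ta = _refine_peak(ts, comp_a)
    tb = _refine_peak(ts, comp_b)
    d = (tb - ta) % period
    if d >= period / 2:
        d -= period
    return d


def _refine_peak(ts, values):
    k = int(np.argmax(values))
    if 0 < k < len(ts) - 1:
        # parabolic interpolation through the three samples around the max
        y0, y1, y2 = values[k - 1], values[k], values[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            return ts[k] + shift * (ts[1] - ts[0])
    return ts[k]


def frequency_sweep(
    model_factory: Callable[[float], ModelSystem],
    values: Sequence[float],
    param_name: str = "alpha",
    x0: Sequence[float] | None = None,
    warm_start: bool = True,
    **cycle_kwargs,
) -> pd.DataFrame:
    """Extract one cycle per parameter value; failed points are flagged.

    Each solve is warm-started from the previous cycle's state so the sweep
    follows the branch of stable periodic solutions.
    """
    rows = []
    state = None if x0 is None else np.asarray(x0, dtype=float)
    for v in values:
        model = model_factory(v)
        try:
            summary = extract_cycle(model, x0=state, **cycle_kwargs)
        except OscillabError as err:
            rows.append(
                {param_name: v, "omega": np.nan, "period": np.nan,
                 "amplitude_x1": np.nan, "converged": False, "note": str(err)}
            )
            continue
        if warm_start:
            state = summary.cycle_state
        rows.append(
            {
                param_name: v,
                "omega": summary.frequency,
                "period": summary.period,
                "amplitude_x1": float(summary.amplitude[0]),
                "converged": True,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def average_frequency(cycles: Sequence[CycleSummary]) -> tuple[float, float]:
    """Arithmetic mean frequency and mean period of decoupled cells.

    Both are returned: the period of the mean frequency is the harmonic mean
    of the individual periods, which differs from the mean period in general.
    """
    if not cycles:
        raise ValidationError("average_frequency needs at least one cycle")
    omega_ave = float(np.mean([c.frequency for c in cycles]))
    t_ave = float(np.mean([c.period for c in cycles]))
    return omega_ave, t_ave


def find_matching_coupling(
    model_factory: Callable[[float], ModelSystem],
    c_bracket: tuple[float, float],
    omega_ave: float,
    n_scan: int = 6,
    xtol: float = 1e-4,
    **cycle_kwargs,
) -> float:
    """Coupling strength at which the collective frequency equals a target.

    Scans ``omega_c(c) - omega_ave`` over the bracket for a sign change, then
    refines by bracketed root finding over cycle extractions.
    """
    lo, hi = c_bracket
    warm = {"state": cycle_kwargs.pop("x0", None)}

    def gap(c: float) -> float:
        summary = extract_cycle(model_factory(c), x0=warm["state"], **cycle_kwargs)
        warm["state"] = summary.cycle_state
        return summary.frequency - omega_ave

    grid = np.linspace(lo, hi, n_scan + 1)
    vals = [gap(c) for c in grid]
    for c0, c1, v0, v1 in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if np.sign(v0) != np.sign(v1):
            return float(brentq(gap, c0, c1, xtol=xtol))
    sampled = ", ".join(f"({c:.4g}: {v:+.4g})" for c, v in zip(grid, vals))
    raise NoCycleError(
        f"omega_c - omega_ave does not change sign on the bracket; sampled {sampled}"
    )
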