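"""Streaming control-chart statistics and their control limits.

Five chart kinds share one interface:

* ``shewhart`` — plots the raw observation, limits ``mu0 ± H * sigma``.
* ``ma`` — moving average of span ``w``; during warm-up (``t < w``) the
  statistic averages all observations so far and the limits widen
  accordingly (variance ``sigma^2 / min(t, w)``).
* ``ewma`` — exponentially weighted moving average
  ``Z_t = lambda * x_t + (1 - lambda) * Z_{t-1}``, ``Z_0 = mu0``; limits use
  either the exact finite-time variance
  ``sigma^2 * lam/(2-lam) * (1 - (1-lam)^(2t))`` (``limit_mode =
  "time_varying"``) or its stationary limit (``"asymptotic"``).
* ``ma_ewma`` — the EWMA values are averaged over a window of span ``w``;
  limit variance ``(sigma^2 / min(t, w)) * lam/(2-lam)``.
* ``ewma_ma`` — the mixed EWMA-MA chart. With ``smoothing="ma"`` (default)
  the EWMA recursion is driven by the span-``w`` moving average of the
  observations; with ``smoothing="raw"`` it is driven by the raw
  observations (the variant under which the published reference tables for
  this chart reproduce — see docs/methods.md). Either way the limit
  variance is ``(sigma^2 / w) * lam/(2-lam)``, optionally multiplied by the
  EWMA warm-up factor in ``time_varying`` mode.

A signal is declared on a strict excursion (statistic strictly outside
``[lcl, ucl]``); equality with a limit is not a signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

__all__ = [
    "CHART_KINDS",
    "ChartSpec",
    "ChartState",
    "ControlLimits",
    "make_chart",
    "initial_state",
    "ma_update",
    "ewma_update",
    "ewma_ma_update",
    "ma_ewma_update",
    "variance_at",
    "limits_at",
    "step",
]

CHART_KINDS = ("shewhart", "ma", "ewma", "ma_ewma", "ewma_ma")


@dataclass(frozen=True)
class ChartSpec:
    """Immutable chart parameters.

    ``H`` multiplies the square root of the time-``t`` variance term to give
    the half-width of the limits. ``scale`` is the standard deviation of the
    per-period input (``sigma0 / sqrt(n)`` for subgroup means of size n).
    """

    kind: str
    lambda_: float = 1.0
    w: int = 1
    H: float = 3.0
    center: float = 0.0
    scale: float = 1.0
    limit_mode: str = "time_varying"
    smoothing: str = "ma"


@dataclass
class ChartState:
    """Streaming state: time index, EWMA value, and the averaging buffer."""

    t: int = 0
    z: float = 0.0
    buffer: List[float] = field(default_factory=list)
    stat: float = float("nan")


@dataclass(frozen=True)
class ControlLimits:
    lcl: float
    ucl: float
    variance_used: float


def make_chart(
    kind: str,
    lambda_: float = 1.0,
    w: int = 1,
    H: float = 3.0,
    center: float = 0.0,
    scale: float = 1.0,
    limit_mode: Optional[str] = None,
    smoothing: str = "ma",
) -> ChartSpec:
    """Validate parameters and build a :class:`ChartSpec`.

    ``limit_mode`` defaults to ``"time_varying"`` for the EWMA chart and
    ``"asymptotic"`` for the EWMA-MA chart (whose published limit formula is
    constant in time); it is ignored by the other kinds.
    """
    if kind not in CHART_KINDS:
        raise ValueError(f"unknown chart kind {kind!r}; expected one of {CHART_KINDS}")
    if not (0.0 < lambda_ <= 1.0):
        raise ValueError(f"lambda_ must be in (0, 1], got {lambda_}")
    if int(w) != w or w < 1:
        raise ValueError(f"w must be a positive integer, got {w}")
    if H < 0:
        raise ValueError(f"H must be non-negative, got {H}")
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if limit_mode is None:
        limit_mode = "asymptotic" if kind == "ewma_ma" else "time_varying"
    if limit_mode not in ("time_varying", "asymptotic"):
        raise ValueError(f"unknown limit_mode {limit_mode!r}")
    if smoothing not in ("ma", "raw"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    return ChartSpec(
        kind=kind,
        lambda_=float(lambda_),
        w=int(w),
        H=float(H),
        center=float(center),
        scale=float(scale),
        limit_mode=limit_mode,
        smoothing=smoothing,
    )


def initial_state(chart: ChartSpec) -> ChartState:
    """State before any observation: t = 0, Z_0 = center, empty buffer."""
    return ChartState(t=0, z=chart.center, buffer=[], stat=float("nan"))


def _windowed_mean(buffer: List[float], x: float, w: int) -> Tuple[List[float], float]:
    buf = buffer + [x]
    if len(buf) > w:
        buf = buf[-w:]
    return buf, sum(buf) / len(buf)


def ma_update(state: ChartState, x: float, w: int) -> Tuple[ChartState, float]:
    """Moving average of the last ``min(t, w)`` observations."""
    buf, stat = _windowed_mean(state.buffer, x, w)
    return ChartState(t=state.t + 1, z=state.z, buffer=buf, stat=stat), stat


def ewma_update(state: ChartState, x: float, lambda_: float) -> Tuple[ChartState, float]:
    """One step of the EWMA recursion."""
    z = lambda_ * x + (1.0 - lambda_) * state.z
    return ChartState(t=state.t + 1, z=z, buffer=list(state.buffer), stat=z), z


def ewma_ma_update(
    state: ChartState, x: float, lambda_: float, w: int
) -> Tuple[ChartState, float]:
    """EWMA driven by the span-``w`` moving average of the observations."""
    buf, ma = _windowed_mean(state.buffer, x, w)
    z = lambda_ * ma + (1.0 - lambda_) * state.z
    return ChartState(t=state.t + 1, z=z, buffer=buf, stat=z), z


def ma_ewma_update(
    state: ChartState, x: float, lambda_: float, w: int
) -> Tuple[ChartState, float]:
    """Span-``w`` moving average of the EWMA values."""
    z = lambda_ * x + (1.0 - lambda_) * state.z
    buf, stat = _windowed_mean(state.buffer, z, w)
    out = ChartState(t=state.t + 1, z=z, buffer=buf, stat=stat)
    return out, stat


def variance_at(chart: ChartSpec, t: int) -> float:
    """The variance term under the square root of the limits at time ``t``."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    s2 = chart.scale**2
    lam = chart.lambda_
    mix = lam / (2.0 - lam)
    if chart.kind == "shewhart":
        return s2
    if chart.kind == "ma":
        return s2 / min(t, chart.w)
    if chart.kind == "ewma":
        if chart.limit_mode == "time_varying":
            return s2 * mix * (1.0 - (1.0 - lam) ** (2 * t))
        return s2 * mix
    if chart.kind == "ma_ewma":
        return (s2 / min(t, chart.w)) * mix
    # ewma_ma
    v = (s2 / chart.w) * mix
    if chart.limit_mode == "time_varying":
        v *= 1.0 - (1.0 - lam) ** (2 * t)
    return v


def limits_at(chart: ChartSpec, t: int) -> ControlLimits:
    """Control limits ``center ± H * sqrt(variance_at(chart, t))``."""
    v = variance_at(chart, t)
    hw = chart.H * v**0.5
    return ControlLimits(lcl=chart.center - hw, ucl=chart.center + hw, variance_used=v)


def step(
    chart: ChartSpec, state: ChartState, x: float
) -> Tuple[ChartState, float, ControlLimits, bool]:
    """Consume one observation; return (state, statistic, limits, signal)."""
    if chart.kind == "shewhart":
        state = ChartState(t=state.t + 1, z=state.z, buffer=[], stat=x)
        stat = x
    elif chart.kind == "ma":
        state, stat = ma_update(state, x, chart.w)
    elif chart.kind == "ewma":
        state, stat = ewma_update(state, x, chart.lambda_)
    elif chart.kind == "ma_ewma":
        state, stat = ma_ewma_update(state, x, chart.lambda_, chart.w)
    elif chart.kind == "ewma_ma" and chart.smoothing == "raw":
        state, stat = ewma_update(state, x, chart.lambda_)
    else:
        state, stat = ewma_ma_update(state, x, chart.lambda_, chart.w)
    lim = limits_at(chart, state.t)
    signal = stat < lim.lcl or stat > lim.ucl
    return state, stat, lim, signal
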