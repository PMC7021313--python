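"""Phase-II monitoring of an observed series with known in-control parameters.

A configured chart is applied sequentially to a labeled univariate series
(for example annual river flows or GDP growth rates); every period's
statistic, limits, and signal flag are recorded, and the label of the first
out-of-control period is the headline output. In-control mean and standard
deviation are user-supplied — no phase-I estimation is performed.

The classic annual Nile flow series (1871-1930), used as the worked
application, ships with the package; see :func:`load_nile`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .charts import ChartSpec, initial_state, step

__all__ = [
    "ObservedSeries",
    "MonitoringResult",
    "monitor_series",
    "first_signal",
    "read_series_csv",
    "load_nile",
]


@dataclass(frozen=True)
class ObservedSeries:
    """An ordered, labeled series with known in-control mean and SD."""

    labels: tuple
    values: np.ndarray
    mu0: float
    sigma0: float

    def __post_init__(self):
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must have equal length")
        if len(self.labels) == 0:
            raise ValueError("series is empty")
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        if list(self.labels) != sorted(self.labels):
            raise ValueError("labels must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = [self.labels[i] for i in np.where(~np.isfinite(self.values))[0]]
            raise ValueError(f"non-finite values at labels {bad}; imputation is not supported")


@dataclass(frozen=True)
class MonitoringResult:
    """Per-period trace plus the earliest signalling label (or ``None``)."""

    records: pd.DataFrame  # columns: label, input, statistic, lcl, ucl, signal
    first_signal_label: Optional[object]


def monitor_series(chart: ChartSpec, series: ObservedSeries) -> MonitoringResult:
    """Run the chart over the whole series, recording all signals.

    The chart should be centered at the series' in-control parameters
    (``center = mu0``, ``scale = sigma0``); monitoring continues past the
    first signal.
    """
    if not np.isclose(chart.center, series.mu0) or not np.isclose(chart.scale, series.sigma0):
        raise ValueError(
            "chart center/scale must match the series in-control parameters "
            f"(chart: {chart.center}/{chart.scale}, series: {series.mu0}/{series.sigma0})"
        )
    state = initial_state(chart)
    rows = []
    first: Optional[object] = None
    for label, x in zip(series.labels, series.values):
        state, stat, lim, signal = step(chart, state, float(x))
        rows.append(
            {
                "label": label,
                "input": float(x),
                "statistic": stat,
                "lcl": lim.lcl,
                "ucl": lim.ucl,
                "signal": bool(signal),
            }
        )
        if signal and first is None:
            first = label
    return MonitoringResult(records=pd.DataFrame(rows), first_signal_label=first)


def first_signal(result: MonitoringResult) -> Optional[object]:
    """Earliest signalling label of a monitoring result, or ``None``."""
    sig = result.records.loc[result.records["signal"], "label"]
    return None if sig.empty else sig.iloc[0]


def read_series_csv(path, mu0: float, sigma0: float) -> ObservedSeries:
    """Read a ``label,value`` CSV into an :class:`ObservedSeries`.

    Labels must be unique and in increasing order; blank or non-numeric
    value cells are rejected with the offending label named.
    """
    df = pd.read_csv(path, comment="#")
    if list(df.columns[:2]) != ["label", "value"]:
        raise ValueError(f"expected columns 'label,value', got {list(df.columns)}")
    values = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = df["label"][np.isnan(values)].tolist()
        raise ValueError(f"missing or non-numeric value at labels {bad}")
    return ObservedSeries(
        labels=tuple(df["label"].tolist()), values=values, mu0=float(mu0), sigma0=float(sigma0)
    )


def load_nile(mu0: float = 1100.0, sigma0: float = 125.0) -> ObservedSeries:
    """The annual Nile flow series 1871-1930 (10^8 m^3 units of the classic
    published record), with the conventional pre-change mean 1100 and SD 125."""
    ref = resources.files("spcmix.data") / "nile_flow_1871_1930.csv"
    with resources.as_file(ref) as path:
        return read_series_csv(path, mu0=mu0, sigma0=sigma0)
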