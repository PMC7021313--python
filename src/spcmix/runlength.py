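"""Monte-Carlo estimation of the run-length distribution.

The run length of a chart on a stream of observations is the 1-based index
of the first observation whose statistic falls strictly outside the control
limits. Runs that never signal within ``max_steps`` observations are
censored at ``max_steps`` and counted in ``n_censored`` (they still
contribute ``max_steps`` to the mean, so summaries are mildly biased low
when censoring is non-negligible).

Replications are simulated in fixed-size batches; each batch draws its
observations from a child stream spawned from ``numpy.random.SeedSequence
(seed)``, so results depend only on ``(seed, n_reps, max_steps)`` and are
invariant to how the batches are executed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple, Union

import numpy as np
import pandas as pd

from .charts import ChartSpec, initial_state, step, variance_at
from .distributions import DistributionSpec, sample, with_delta

__all__ = [
    "RunLengthSummary",
    "run_length",
    "simulate_run_lengths",
    "estimate_run_length",
    "summarize",
    "arl_curve",
]

#: replications per vectorized batch (fixed so the seed list is a pure
#: function of n_reps)
BATCH_SIZE = 16384


@dataclass(frozen=True)
class RunLengthSummary:
    """Summary of a simulated run-length sample.

    ``sdrl`` uses the population (divide-by-N) form and ``se_arl`` equals
    ``sdrl / sqrt(n_reps)`` exactly. ``mrl`` is the sample median (mean of
    the two central order statistics for even N).
    """

    n_reps: int
    arl: float
    sdrl: float
    mrl: float
    se_arl: float
    max_steps: int
    n_censored: int
    seed: int


def run_length(
    chart: ChartSpec,
    dist: DistributionSpec,
    stream: Union[int, np.random.Generator],
    max_steps: int = 10_000,
) -> Tuple[int, bool]:
    """Simulate a single run; returns (run_length, censored).

    This is the streaming scalar counterpart of
    :func:`simulate_run_lengths`, built on :func:`spcmix.charts.step`.
    """
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    rng = np.random.default_rng(stream) if not isinstance(stream, np.random.Generator) else stream
    state = initial_state(chart)
    for t in range(1, max_steps + 1):
        x = float(sample(dist, 1, rng)[0])
        state, _, _, signal = step(chart, state, x)
        if signal:
            return t, False
    return max_steps, True


def _simulate_batch(
    chart: ChartSpec,
    dist: DistributionSpec,
    n: int,
    rng: np.random.Generator,
    max_steps: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized run lengths for one batch of ``n`` replications.

    All active replications advance in lockstep; finished ones are removed
    from the state arrays at each signalling step.
    """
    kind, lam, w = chart.kind, chart.lambda_, chart.w
    center = chart.center
    rl = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    z = np.full(n, center, dtype=np.float64)
    needs_buf = kind in ("ma", "ma_ewma") or (kind == "ewma_ma" and chart.smoothing == "ma")
    buf = np.zeros((w, n), dtype=np.float64) if needs_buf else None
    bsum = np.zeros(n, dtype=np.float64)
    t = 0
    while active.size and t < max_steps:
        t += 1
        na = active.size
        x = sample(dist, na, rng)
        if kind == "shewhart":
            stat = x
        elif kind == "ewma" or (kind == "ewma_ma" and chart.smoothing == "raw"):
            z[:na] = lam * x + (1.0 - lam) * z[:na]
            stat = z[:na]
        else:
            if kind == "ma_ewma":
                z[:na] = lam * x + (1.0 - lam) * z[:na]
                new = z[:na]
            else:
                new = x
            idx = (t - 1) % w
            if t > w:
                bsum[:na] -= buf[idx, :na]
            buf[idx, :na] = new
            bsum[:na] += new
            ma = bsum[:na] / min(t, w)
            if kind == "ma":
                stat = ma
            else:  # ewma_ma, smoothing="ma"
                z[:na] = lam * ma + (1.0 - lam) * z[:na]
                stat = z[:na]
        hw = chart.H * variance_at(chart, t) ** 0.5
        sig = np.abs(stat - center) > hw
        if sig.any():
            rl[active[sig]] = t
            keep = ~sig
            active = active[keep]
            m = active.size
            z[:m] = z[:na][keep]
            bsum[:m] = bsum[:na][keep]
            if needs_buf:
                buf[:, :m] = buf[:, :na][:, keep]
    censored = np.zeros(n, dtype=bool)
    if active.size:
        rl[active] = max_steps
        censored[active] = True
    return rl, censored


def simulate_run_lengths(
    chart: ChartSpec,
    dist: DistributionSpec,
    n_reps: int,
    seed: int,
    max_steps: int = 10_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_reps`` independent run lengths; returns (rl, censored)."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    sizes = [BATCH_SIZE] * (n_reps // BATCH_SIZE)
    if n_reps % BATCH_SIZE:
        sizes.append(n_reps % BATCH_SIZE)
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    parts = [
        _simulate_batch(chart, dist, m, np.random.default_rng(ss), max_steps)
        for m, ss in zip(sizes, children)
    ]
    rl = np.concatenate([p[0] for p in parts])
    cens = np.concatenate([p[1] for p in parts])
    return rl, cens


def summarize(
    rl: np.ndarray, censored: np.ndarray, max_steps: int, seed: int
) -> RunLengthSummary:
    n = rl.size
    arl = float(rl.mean())
    sdrl = float(rl.std(ddof=0))
    return RunLengthSummary(
        n_reps=n,
        arl=arl,
        sdrl=sdrl,
        mrl=float(np.median(rl)),
        se_arl=sdrl / n**0.5,
        max_steps=max_steps,
        n_censored=int(censored.sum()),
        seed=seed,
    )


def estimate_run_length(
    chart: ChartSpec,
    dist: DistributionSpec,
    n_reps: int,
    seed: int,
    max_steps: int = 10_000,
) -> RunLengthSummary:
    """ARL / SDRL / MRL and their precision from ``n_reps`` replications."""
    rl, cens = simulate_run_lengths(chart, dist, n_reps, seed, max_steps)
    return summarize(rl, cens, max_steps, seed)


def arl_curve(
    chart: ChartSpec,
    dist: DistributionSpec,
    deltas: Iterable[float],
    n_reps: int,
    seed: int,
    max_steps: int = 10_000,
) -> pd.DataFrame:
    """Run-length summaries over a grid of shift sizes.

    The chart (including its H) is held fixed across the grid, as when a
    chart calibrated in control is evaluated out of control. One child seed
    is spawned per shift.
    """
    deltas = list(deltas)
    if not deltas:
        raise ValueError("deltas must be non-empty")
    child_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(len(deltas))
    ]
    rows = []
    for d, s in zip(deltas, child_seeds):
        summ = estimate_run_length(chart, with_delta(dist, d), n_reps, s, max_steps)
        rows.append(
            {
                "delta": d,
                "arl": summ.arl,
                "se_arl": summ.se_arl,
                "sdrl": summ.sdrl,
                "mrl": summ.mrl,
                "n_reps": summ.n_reps,
                "n_censored": summ.n_censored,
                "seed": summ.seed,
            }
        )
    return pd.DataFrame(rows)
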