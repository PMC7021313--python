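"""Calibration of the control-limit coefficient H to a target in-control ARL.

The search exploits a structural fact: for a fixed stream of observations
the chart statistic does not depend on H, so the run length at coefficient
H is the first time the normalized excursion

    D_t = |stat_t - center| / sqrt(variance_at(chart, t))

exceeds H. One simulation pass therefore determines the run length for
*every* H up to a cap: it suffices to record, per replication, the strictly
increasing sequence of running-maximum records of D_t together with their
times. The empirical ARL is then an exactly evaluable, monotone
non-decreasing step function of H (common random numbers by construction),
and the root ``ARL0(H) = target`` is found by bisection at no further
simulation cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .charts import ChartSpec, make_chart, variance_at
from .distributions import DistributionSpec, frozen_in_control, sample

__all__ = [
    "CalibrationResult",
    "RunLengthProfiles",
    "simulate_profiles",
    "calibrate_H",
    "closed_form_shewhart_H",
]


@dataclass(frozen=True)
class CalibrationResult:
    H: float
    achieved_arl0: float
    target_arl0: float
    bracket: Tuple[float, float]
    n_reps: int
    seed: int
    tolerance: float


class RunLengthProfiles:
    """Per-replication running-max records of the normalized excursion.

    For any coefficient ``0 <= H < h_cap``, :meth:`run_lengths` returns the
    exact simulated run lengths (censored at ``max_steps``) that a chart
    with that H would have produced on the stored streams.
    """

    def __init__(self, rep, t, d, n_reps, max_steps, h_cap):
        order = np.lexsort((t, rep))
        self.rep = rep[order]
        self.t = t[order]
        self.d = d[order]
        self.n_reps = n_reps
        self.max_steps = max_steps
        self.h_cap = h_cap
        # group boundaries per replication (replications with no record are
        # possible only if the statistic never left the center exactly)
        self._starts = np.searchsorted(self.rep, np.arange(n_reps))
        self._ends = np.searchsorted(self.rep, np.arange(n_reps), side="right")

    def run_lengths(self, H: float) -> np.ndarray:
        if H >= self.h_cap:
            raise ValueError(f"H={H} not covered by profiles (cap {self.h_cap})")
        exceed = self.d > H
        t_mask = np.where(exceed, self.t, np.int64(self.max_steps))
        rl = np.full(self.n_reps, self.max_steps, dtype=np.int64)
        nonempty = self._ends > self._starts
        mins = np.minimum.reduceat(t_mask, self._starts[nonempty])
        rl[nonempty] = mins
        return rl

    def arl(self, H: float) -> float:
        return float(self.run_lengths(H).mean())


def simulate_profiles(
    chart: ChartSpec,
    dist: DistributionSpec,
    n_reps: int,
    seed: int,
    max_steps: int = 10_000,
    h_cap: float = 20.0,
) -> RunLengthProfiles:
    """One vectorized pass recording running-max records of D_t.

    A replication is retired once its running max exceeds ``h_cap`` (its
    run length is then known for every H below the cap) or at
    ``max_steps``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    kind, lam, w = chart.kind, chart.lambda_, chart.w
    center = chart.center
    active = np.arange(n_reps)
    z = np.full(n_reps, center, dtype=np.float64)
    needs_buf = kind in ("ma", "ma_ewma") or (kind == "ewma_ma" and chart.smoothing == "ma")
    buf = np.zeros((w, n_reps), dtype=np.float64) if needs_buf else None
    bsum = np.zeros(n_reps, dtype=np.float64)
    rmax = np.zeros(n_reps, dtype=np.float64)
    rec_rep, rec_t, rec_d = [], [], []
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
            else:
                z[:na] = lam * ma + (1.0 - lam) * z[:na]
                stat = z[:na]
        d = np.abs(stat - center) / variance_at(chart, t) ** 0.5
        newrec = d > rmax[:na]
        if newrec.any():
            rec_rep.append(active[newrec])
            rec_t.append(np.full(int(newrec.sum()), t, dtype=np.int64))
            rec_d.append(d[newrec])
            rmax[:na] = np.maximum(rmax[:na], d)
        done = rmax[:na] > h_cap
        if done.any():
            keep = ~done
            active = active[keep]
            m = active.size
            z[:m] = z[:na][keep]
            bsum[:m] = bsum[:na][keep]
            rmax[:m] = rmax[:na][keep]
            if needs_buf:
                buf[:, :m] = buf[:, :na][:, keep]
    rep = np.concatenate(rec_rep) if rec_rep else np.empty(0, dtype=np.int64)
    tt = np.concatenate(rec_t) if rec_t else np.empty(0, dtype=np.int64)
    dd = np.concatenate(rec_d) if rec_d else np.empty(0, dtype=np.float64)
    return RunLengthProfiles(rep, tt, dd, n_reps, max_steps, h_cap)


def calibrate_H(
    kind: str,
    lambda_: float,
    w: int,
    dist: DistributionSpec,
    target_arl0: float = 370.0,
    n_reps: int = 20_000,
    seed: int = 0,
    tolerance: float = 2.0,
    max_steps: int = 10_000,
    limit_mode: Optional[str] = None,
    smoothing: str = "ma",
    h_cap: float = 2.0,
    h_max: float = 80.0,
) -> CalibrationResult:
    """Find H with simulated in-control ARL equal to ``target_arl0``.

    Bisection on the exact common-random-number ARL step function from one
    :func:`simulate_profiles` pass. The cap starts small and grows by 25%
    (with the pass redone) until it brackets the target; stopping at the
    first bracketing cap keeps the pass cost near ``ARL(h_cap)`` rather
    than the censoring horizon.
    """
    if target_arl0 <= 1:
        raise ValueError(f"target_arl0 must exceed 1, got {target_arl0}")
    if abs(dist.delta) > 0:
        raise ValueError("calibration requires the in-control (delta = 0) distribution")
    chart = make_chart(
        kind, lambda_=lambda_, w=w, H=0.0, center=dist.mu0, scale=dist.sigma0,
        limit_mode=limit_mode, smoothing=smoothing,
    )
    profiles = simulate_profiles(chart, dist, n_reps, seed, max_steps, h_cap)
    while profiles.arl(profiles.h_cap * 0.999999) < target_arl0:
        h_cap *= 1.25
        if h_cap > h_max:
            raise RuntimeError(
                f"target ARL0={target_arl0} not reachable with H <= {h_max} "
                f"(check max_steps={max_steps} censoring)"
            )
        profiles = simulate_profiles(chart, dist, n_reps, seed, max_steps, h_cap)
    lo, hi = 0.0, h_cap * 0.999999
    mid = 0.5 * (lo + hi)
    achieved = profiles.arl(mid)
    while hi - lo >= 1e-3:
        mid = 0.5 * (lo + hi)
        achieved = profiles.arl(mid)
        if abs(achieved - target_arl0) <= tolerance:
            break
        if achieved < target_arl0:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(
        H=mid,
        achieved_arl0=achieved,
        target_arl0=target_arl0,
        bracket=(lo, hi),
        n_reps=n_reps,
        seed=seed,
        tolerance=tolerance,
    )


def closed_form_shewhart_H(dist: DistributionSpec, target_arl0: float = 370.0) -> float:
    """Exact Shewhart coefficient from the in-control tail probabilities.

    Solves ``P(X < mu0 - H*sigma0) + P(X > mu0 + H*sigma0) = 1/target_arl0``
    on the family's closed-form CDF. For skewed families whose lower limit
    falls below the support only the upper tail contributes.
    """
    if target_arl0 <= 1:
        raise ValueError(f"target_arl0 must exceed 1, got {target_arl0}")
    fr = frozen_in_control(dist)
    p = 1.0 / target_arl0

    def excess(H: float) -> float:
        return fr.cdf(dist.mu0 - H * dist.sigma0) + fr.sf(dist.mu0 + H * dist.sigma0) - p

    lo, hi = 0.0, 10.0
    while excess(hi) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("could not bracket the Shewhart coefficient")
    return float(optimize.brentq(excess, lo, hi, xtol=1e-10))
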