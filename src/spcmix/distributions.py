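"""Sampling families for run-length simulation.

Six univariate families are supported (normal, Laplace, logistic, Student-t,
exponential, gamma), each with closed-form in-control moments and a
standardized mean shift ``mu1 = mu0 + delta * sigma0``.

Two conventions are configurable:

* ``scale_convention`` — whether ``sigma0`` is the distribution's standard
  deviation (``"sd"``, default) or its raw scale parameter
  (``"scale_param"``). The two coincide for the normal and exponential
  families.
* ``shift_mode`` — how the out-of-control state is realized.
  ``"location"`` translates the in-control draws by ``delta * sigma0``
  (shape and spread unchanged). ``"mean"`` re-parameterizes the family so
  its mean equals ``mu1`` (for the exponential this is Exp(mean ``mu1``);
  for the gamma the shape becomes ``mu1 / theta`` at fixed scale ``theta``;
  the spread changes with the mean, as is natural for these skewed
  families). For symmetric location-scale families the two modes coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "make_distribution",
    "sample",
    "with_delta",
    "frozen_in_control",
]

FAMILIES = ("normal", "laplace", "logistic", "student_t", "exponential", "gamma")

#: families whose support is bounded below; only delta >= 0 shifts are meaningful
_SKEWED = ("exponential", "gamma")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling family with in-control moments and a standardized shift.

    Attributes
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Family-specific parameters: ``(loc, scale)`` for normal / laplace /
        logistic, ``(df,)`` for student_t, ``(rate,)`` for exponential,
        ``(shape, scale)`` for gamma.
    delta : float
        Dimensionless shift multiplier.
    mu0, sigma0, mu1 : float
        In-control mean, in-control scale (under ``scale_convention``), and
        shifted mean ``mu0 + delta * sigma0``.
    """

    family: str
    params: Tuple[float, ...]
    delta: float
    mu0: float
    sigma0: float
    mu1: float
    scale_convention: str = "sd"
    shift_mode: str = "location"


def _moments(family: str, params: Tuple[float, ...]) -> Tuple[float, float, float]:
    """Return (mu0, sd, scale_param) from closed-form moments."""
    if family == "normal":
        loc, scale = params
        return loc, scale, scale
    if family == "laplace":
        loc, scale = params
        return loc, scale * math.sqrt(2.0), scale
    if family == "logistic":
        loc, scale = params
        return loc, scale * math.pi / math.sqrt(3.0), scale
    if family == "student_t":
        (df,) = params
        return 0.0, math.sqrt(df / (df - 2.0)), 1.0
    if family == "exponential":
        (rate,) = params
        return 1.0 / rate, 1.0 / rate, 1.0 / rate
    if family == "gamma":
        shape, scale = params
        return shape * scale, math.sqrt(shape) * scale, scale
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def make_distribution(
    family: str,
    params,
    delta: float = 0.0,
    scale_convention: str = "sd",
    shift_mode: str = "location",
) -> DistributionSpec:
    """Build a validated :class:`DistributionSpec`.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : sequence of float
        See :class:`DistributionSpec`.
    delta : float
        Standardized shift; ``mu1 = mu0 + delta * sigma0``. Must be >= 0 for
        the exponential and gamma families.
    """
    params = tuple(float(p) for p in params)
    if scale_convention not in ("sd", "scale_param"):
        raise ValueError(f"unknown scale_convention {scale_convention!r}")
    if shift_mode not in ("location", "mean"):
        raise ValueError(f"unknown shift_mode {shift_mode!r}")

    if family in ("normal", "laplace", "logistic", "gamma"):
        if len(params) != 2:
            raise ValueError(f"{family} takes (loc/shape, scale), got {params}")
        if params[1] <= 0:
            raise ValueError(f"{family} scale must be positive, got {params[1]}")
        if family == "gamma" and params[0] <= 0:
            raise ValueError(f"gamma shape must be positive, got {params[0]}")
    elif family == "student_t":
        if len(params) != 1:
            raise ValueError(f"student_t takes (df,), got {params}")
        if params[0] <= 2:
            raise ValueError(f"student_t needs df > 2 for a finite SD, got {params[0]}")
    elif family == "exponential":
        if len(params) != 1:
            raise ValueError(f"exponential takes (rate,), got {params}")
        if params[0] <= 0:
            raise ValueError(f"exponential rate must be positive, got {params[0]}")
    else:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")

    if family in _SKEWED and delta < 0:
        raise ValueError(f"{family} supports only delta >= 0 shifts, got {delta}")

    mu0, sd, scale_param = _moments(family, params)
    sigma0 = sd if scale_convention == "sd" else scale_param
    mu1 = mu0 + delta * sigma0
    if shift_mode == "mean" and family in _SKEWED and mu1 <= 0:
        raise ValueError(f"mean-mode shift needs mu1 > 0, got {mu1}")
    return DistributionSpec(
        family=family,
        params=params,
        delta=float(delta),
        mu0=mu0,
        sigma0=sigma0,
        mu1=mu1,
        scale_convention=scale_convention,
        shift_mode=shift_mode,
    )


def with_delta(spec: DistributionSpec, delta: float) -> DistributionSpec:
    """Return a copy of ``spec`` at a different shift size."""
    if spec.family in _SKEWED and delta < 0:
        raise ValueError(f"{spec.family} supports only delta >= 0 shifts, got {delta}")
    return replace(spec, delta=float(delta), mu1=spec.mu0 + float(delta) * spec.sigma0)


def sample(spec: DistributionSpec, count: int, stream: np.random.Generator) -> np.ndarray:
    """Draw ``count`` i.i.d. observations with mean ``mu1``.

    In ``"location"`` mode the in-control draws are translated by
    ``delta * sigma0``; in ``"mean"`` mode skewed families are
    re-parameterized so their mean equals ``mu1`` (see module docstring).
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    f, p = spec.family, spec.params
    if spec.shift_mode == "mean" and f == "exponential":
        return stream.exponential(spec.mu1, count)
    if spec.shift_mode == "mean" and f == "gamma":
        theta = p[1]
        return stream.gamma(spec.mu1 / theta, theta, count)
    shift = spec.delta * spec.sigma0
    if f == "normal":
        return p[0] + shift + p[1] * stream.standard_normal(count)
    if f == "laplace":
        return stream.laplace(p[0] + shift, p[1], count)
    if f == "logistic":
        return stream.logistic(p[0] + shift, p[1], count)
    if f == "student_t":
        return shift + stream.standard_t(p[0], count)
    if f == "exponential":
        return shift + stream.exponential(1.0 / p[0], count)
    # gamma, location mode
    return shift + stream.gamma(p[0], p[1], count)


def frozen_in_control(spec: DistributionSpec):
    """The in-control (delta = 0) scipy frozen distribution, for exact tails."""
    f, p = spec.family, spec.params
    if f == "normal":
        return stats.norm(p[0], p[1])
    if f == "laplace":
        return stats.laplace(p[0], p[1])
    if f == "logistic":
        return stats.logistic(p[0], p[1])
    if f == "student_t":
        return stats.t(p[0])
    if f == "exponential":
        return stats.expon(scale=1.0 / p[0])
    return stats.gamma(p[0], scale=p[1])
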