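"""Nonlinear calibration between chronological age and the clock's linear scale.

The epigenetic clock ticks fast during development and settles to a constant
rate in adulthood.  Training and prediction therefore operate on a transformed
age scale: logarithmic below an "adult age" knot (default 20 years) and linear
above it.  The transform is continuous and continuously differentiable at the
knot, strictly increasing, and exactly invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationSpec", "transform_age", "inverse_transform_age"]

DEFAULT_ADULT_AGE = 20.0


@dataclass(frozen=True)
class CalibrationSpec:
    """Parameters of the age calibration transform.

    Attributes
    ----------
    adult_age : float
        Knot (in years) where the log branch hands over to the linear
        branch; marks the slowdown of the clock's tick rate. Must be
        finite and positive.
    """

    adult_age: float = DEFAULT_ADULT_AGE

    def __post_init__(self) -> None:
        if not math.isfinite(self.adult_age) or self.adult_age <= 0:
            raise ValueError(f"adult_age must be finite and > 0, got {self.adult_age}")


def transform_age(age, spec: CalibrationSpec | None = None):
    """Map chronological age (years) onto the clock's linear scale.

    F(a) = log(a + 1) - log(adult_age + 1)   for a <= adult_age
    F(a) = (a - adult_age) / (adult_age + 1) for a >  adult_age

    Natural logarithm throughout; both branches have slope
    1/(adult_age + 1) at the knot, so F is C^1. F(adult_age) = 0.

    Accepts scalars or array-likes; returns the same shape.

    Raises
    ------
    ValueError
        If any age is negative or non-finite.
    """
    spec = spec or CalibrationSpec()
    a = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise ValueError("ages must be finite and >= 0")
    k = spec.adult_age
    out = np.where(
        a <= k,
        np.log1p(a) - np.log1p(k),
        (a - k) / (k + 1.0),
    )
    if np.isscalar(age) or np.ndim(age) == 0:
        return float(out)
    return out


def inverse_transform_age(x, spec: CalibrationSpec | None = None):
    """Exact inverse of :func:`transform_age`.

    age = exp(x + log(adult_age + 1)) - 1  for x <= 0
    age = x * (adult_age + 1) + adult_age  for x >  0

    Output is not clipped: strongly positive scores yield ages beyond any
    human lifespan, which is intentional (for example, in cancer tissue).

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    spec = spec or CalibrationSpec()
    xv = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xv)):
        raise ValueError("transformed ages must be finite")
    k = spec.adult_age
    out = np.where(
        xv <= 0,
        np.expm1(xv + np.log1p(k)),
        xv * (k + 1.0) + k,
    )
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out
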