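"""Periodic Gaussian model of diurnal melatonin secretion.

The blood melatonin concentration of a subject over the day is described by
a 24-hour-periodic, bell-shaped curve with four parameters:

    MLT(t) = b1 + b2 * exp( -[ (cos(pi*t/12 - pi*b3/12) - 1) / s ]^2 )

where ``t`` is clock time in hours and the horizontal scale factor

    s = (cos(pi*b4/24) - 1) / sqrt(ln 2)

is chosen so that the full width at half maximum of the nocturnal peak
equals ``b4``.  The parameters carry direct physiological meaning:

* ``b1`` -- minimum (baseline) melatonin concentration [pg/mL],
* ``b2`` -- release amplitude, peak minus baseline [pg/mL],
* ``b3`` -- phase shift: the clock time of the secretion peak [h],
* ``b4`` -- FWHM of the peak, interpreted as estimated sleep duration [h].

The maximum concentration is ``b_max = b1 + b2``, attained at ``t = b3``
(mod 24).  Over one period the curve is unimodal: it decays strictly on
``(b3, b3 + 12)`` and rises strictly on ``(b3 + 12, b3 + 24)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SecretionParams",
    "scale_factor",
    "evaluate_model",
    "peak_time",
    "fwhm_numeric",
    "min_concentration_gap",
]

_SQRT_LN2 = math.sqrt(math.log(2.0))


@dataclass(frozen=True)
class SecretionParams:
    """Parameter vector of the secretion model.

    Invariants are enforced at construction: ``b1 >= 0``, ``b2 >= 0``,
    ``0 <= b3 < 24`` and ``0 < b4 < 12``.  Phase is circular, so values
    of ``b3`` outside ``[0, 24)`` produced upstream should be wrapped
    with ``b3 % 24`` before construction (see :meth:`wrapped`).
    """

    b1: float  # minimum concentration [pg/mL]
    b2: float  # release amplitude [pg/mL]
    b3: float  # phase shift, clock time of peak [h]
    b4: float  # FWHM of the peak / sleep duration [h]

    def __post_init__(self) -> None:
        if not (self.b1 >= 0):
            raise ValueError(f"b1 must be >= 0, got {self.b1}")
        if not (self.b2 >= 0):
            raise ValueError(f"b2 must be >= 0, got {self.b2}")
        if not (0 <= self.b3 < 24):
            raise ValueError(f"b3 must lie in [0, 24), got {self.b3}")
        if not (0 < self.b4 < 12):
            raise ValueError(f"b4 must lie in (0, 12), got {self.b4}")

    @classmethod
    def wrapped(cls, b1: float, b2: float, b3: float, b4: float) -> "SecretionParams":
        """Construct with the circular phase ``b3`` wrapped into [0, 24)."""
        return cls(b1, b2, b3 % 24.0, b4)

    @property
    def b_max(self) -> float:
        """Maximum modelled concentration, ``b1 + b2`` [pg/mL]."""
        return self.b1 + self.b2

    def as_array(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.b4], dtype=float)


def scale_factor(b4: float) -> float:
    """Horizontal scale factor ``s = (cos(pi*b4/24) - 1) / sqrt(ln 2)``.

    Derived from requiring the peak's full width at half maximum to equal
    ``b4``: at ``t = b3 +/- b4/2`` the cosine term equals ``cos(pi*b4/24)``,
    so the squared quotient is exactly ``ln 2`` and the exponential drops
    to one half.  The returned value is negative for all valid ``b4``
    (``cos`` < 1 on (0, pi/2)); the sign is immaterial downstream because
    ``s`` only ever enters squared, but it is kept stable as documented.

    Raises
    ------
    ValueError
        If ``b4`` is outside the open interval (0, 12).
    """
    if not b4 > 0:
        raise ValueError(f"b4 must exceed the lower bound 0, got {b4}")
    if not b4 < 12:
        raise ValueError(f"b4 must lie below the upper bound 12, got {b4}")
    return (math.cos(math.pi * b4 / 24.0) - 1.0) / _SQRT_LN2


def evaluate_model(params: SecretionParams, t):
    """Evaluate the secretion model at clock time(s) ``t`` [h].

    ``t`` may be a scalar or array of any real values; the model is
    defined on the whole real line and 24-hour periodic, so times beyond
    one day fold back automatically.

    Returns concentrations in pg/mL with ``b1 <= MLT(t) <= b1 + b2``.
    """
    s = scale_factor(params.b4)
    t = np.asarray(t, dtype=float)
    phase = np.pi * t / 12.0 - np.pi * params.b3 / 12.0
    z = (np.cos(phase) - 1.0) / s
    out = params.b1 + params.b2 * np.exp(-(z**2))
    return out if out.ndim else float(out)


def peak_time(params: SecretionParams) -> float:
    """Clock time of the secretion maximum, ``b3`` reduced to [0, 24)."""
    return params.b3 % 24.0


def fwhm_numeric(params: SecretionParams) -> float:
    """Numerically measured full width at half maximum of the peak [h].

    Brackets the two half-maximum crossings on either side of the peak
    within ``[b3 - 12, b3 + 12]`` and returns their separation.  By
    construction of the scale factor this equals ``b4``; the routine
    exists as an independent self-check of that identity.
    """
    if params.b2 <= 0:
        raise ValueError("FWHM is undefined for zero amplitude (b2 = 0)")
    half = params.b1 + params.b2 / 2.0

    def f(t: float) -> float:
        return evaluate_model(params, t) - half

    # f > 0 at the peak, f < 0 at the antiphase (model minimum < half max).
    left = brentq(f, params.b3 - 12.0, params.b3, xtol=1e-12)
    right = brentq(f, params.b3, params.b3 + 12.0, xtol=1e-12)
    return right - left


def min_concentration_gap(params: SecretionParams) -> float:
    """Excess of the model's minimum over the baseline ``b1`` [pg/mL].

    The minimum over one period sits at ``t = b3 + 12`` where the cosine
    term equals -1, giving ``b2 * exp(-(2/s)^2)``.  For physiological
    widths (``b4 <= 11``) this gap is a tiny fraction of the amplitude,
    which justifies reading ``b1`` as "the minimum concentration".
    """
    s = scale_factor(params.b4)
    return params.b2 * math.exp(-((2.0 / s) ** 2))
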