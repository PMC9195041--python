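"""Sigmoid enhancement model for breast DCE-MRI kinetic curves.

The model describes the time course of relative signal intensity in a
lesion ROI after bolus contrast injection as a logistic rise followed by
a linear late-phase drift:

    SI(t) = (a + d*t) * logistic(c * (t - b)) + SI0

where ``a`` is the plateau signal change, ``b`` the time of maximum
slope (seconds after injection start), ``c`` the early-phase steepness,
``d`` the late-phase slope (washout when negative) and ``SI0`` the
pre-contrast baseline.  Two BI-RADS enhancement ratios (initial- and
delayed-phase) are computed directly from the sampled curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.special import expit

__all__ = [
    "SigmoidParams",
    "KineticCurve",
    "EnhancementRates",
    "eval_sigmoid",
    "sigmoid_slope",
    "initial_enhancement_rate",
    "delayed_enhancement_rate",
]

Steepness = Literal["rate", "time-constant"]
InitialConvention = Literal["ratio", "relative-difference"]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoid enhancement model.

    Attributes
    ----------
    a : float
        Relative signal change at the plateau (dimensionless when the
        curve is normalized to the pre-contrast value).
    b : float
        Time of maximum slope, in seconds after injection start.
    c : float
        Early-phase steepness.  Under the default ``rate`` convention
        this is a rate in 1/s: larger ``c`` means a steeper rise.
    d : float
        Late-phase slope in relative signal per second.  Negative values
        produce washout; group summaries report it on a 1e-4 scale.
    si0 : float
        Pre-contrast baseline signal (1.0 for normalized curves).
    """

    a: float
    b: float
    c: float
    d: float
    si0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "si0"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v!r}")
        if self.c <= 0:
            raise ValueError(f"steepness c must be positive, got {self.c!r}")
        if self.si0 <= 0:
            raise ValueError(f"baseline si0 must be positive, got {self.si0!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.si0])

    def replace(self, **kw) -> "SigmoidParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class KineticCurve:
    """A 7-phase time--signal-intensity curve from a lesion ROI.

    ``times`` are seconds relative to injection start; exactly one entry
    (the pre-contrast phase) is <= 0.  ``si`` holds the mean ROI signal
    per phase, strictly positive.  ``normalized`` records whether ``si``
    was divided by the pre-contrast value.
    """

    times: tuple
    si: tuple
    normalized: bool = False

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        si = tuple(float(s) for s in self.si)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "si", si)
        t = np.asarray(times)
        s = np.asarray(si)
        if t.size != s.size:
            raise ValueError("times and si must have equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise ValueError("times and si must be finite")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        n_pre = int(np.sum(t <= 0))
        if n_pre != 1:
            raise ValueError(
                f"exactly one pre-contrast time (<= 0) required, got {n_pre}"
            )
        if not np.all(s > 0):
            raise ValueError("signal intensities must be strictly positive")

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def si_array(self) -> np.ndarray:
        return np.asarray(self.si)

    @property
    def pre_index(self) -> int:
        # strictly increasing with exactly one entry <= 0 puts it first
        return 0

    @property
    def si_pre(self) -> float:
        return self.si[self.pre_index]

    def post_si(self, phase: int) -> float:
        """Signal of post-contrast phase ``phase`` (1-based)."""
        idx = self.pre_index + phase
        if phase < 1 or idx >= len(self.si):
            raise IndexError(f"post-contrast phase {phase} out of range")
        return self.si[idx]

    def normalize(self) -> "KineticCurve":
        """Divide all signals by the pre-contrast value."""
        if self.normalized:
            return self
        pre = self.si_pre
        return KineticCurve(
            times=self.times,
            si=tuple(s / pre for s in self.si),
            normalized=True,
        )


@dataclass(frozen=True)
class EnhancementRates:
    """The two BI-RADS kinetic ratios of a curve."""

    initial: float
    delayed: float
    initial_convention: InitialConvention = "ratio"


def _logistic_argument(params: SigmoidParams, t: np.ndarray, steepness: Steepness) -> np.ndarray:
    if steepness == "rate":
        return params.c * (t - params.b)
    if steepness == "time-constant":
        return (t - params.b) / params.c
    raise ValueError(f"unknown steepness convention {steepness!r}")


def eval_sigmoid(params: SigmoidParams, t, steepness: Steepness = "rate"):
    """Evaluate the sigmoid model at time(s) ``t`` (seconds).

    Returns ``(a + d*t) / (1 + exp(-c*(t - b))) + si0`` elementwise.
    The logistic is computed with :func:`scipy.special.expit`, which
    saturates at 0/1 without overflow for large arguments.

    Parameters
    ----------
    params : SigmoidParams
    t : float or array_like
        Time(s) in seconds relative to injection start; must be finite.
    steepness : {"rate", "time-constant"}
        Exponent convention; ``rate`` (default) uses ``exp(-c*(t-b))``,
        ``time-constant`` uses ``exp(-(t-b)/c)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("time values must be finite")
    out = (params.a + params.d * t_arr) * expit(_logistic_argument(params, t_arr, steepness)) + params.si0
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def sigmoid_slope(params: SigmoidParams, t, steepness: Steepness = "rate"):
    """Analytic time derivative of :func:`eval_sigmoid` (signal per second).

    d/dt SI = d*L + (a + d*t) * k * L * (1 - L), with L the logistic and
    k the effective rate (``c`` or ``1/c`` by convention).  At ``t = b``
    with ``d = 0`` this is ``a*c/4``, the maximum slope of the rise.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("time values must be finite")
    rate = params.c if steepness == "rate" else 1.0 / params.c
    lo = expit(_logistic_argument(params, t_arr, steepness))
    out = params.d * lo + (params.a + params.d * t_arr) * rate * lo * (1.0 - lo)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def initial_enhancement_rate(
    curve: KineticCurve, convention: InitialConvention = "ratio"
) -> float:
    """Initial-phase enhancement rate, SI_ph1 relative to SI_pre.

    ``ratio`` returns SI_ph1 / SI_pre; ``relative-difference`` returns
    (SI_ph1 - SI_pre) / SI_pre, i.e. the fractional enhancement.  Both
    conventions appear in the BI-RADS literature; neither is substituted
    for the other silently.
    """
    pre = curve.si_pre
    if pre == 0:
        raise ZeroDivisionError("pre-contrast signal is zero")
    ph1 = curve.post_si(1)
    if convention == "ratio":
        return ph1 / pre
    if convention == "relative-difference":
        return (ph1 - pre) / pre
    raise ValueError(f"unknown initial-rate convention {convention!r}")


def delayed_enhancement_rate(curve: KineticCurve) -> float:
    """Delayed-phase enhancement rate SI_ph2 / SI_ph6.

    Values above 1 indicate washout (late signal below the early peak);
    values below 1 indicate persistent enhancement.
    """
    ph6 = curve.post_si(6)
    if ph6 == 0:
        raise ZeroDivisionError("phase-6 signal is zero")
    return curve.post_si(2) / ph6


def enhancement_rates(
    curve: KineticCurve, convention: InitialConvention = "ratio"
) -> EnhancementRates:
    """Convenience wrapper returning both BI-RADS ratios."""
    return EnhancementRates(
        initial=initial_enhancement_rate(curve, convention),
        delayed=delayed_enhancement_rate(curve),
        initial_convention=convention,
    )
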