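"""Gamma-variate contrast-transit model.

A first-pass bolus of iodinated contrast traversing a voxel produces a
time-intensity curve that is well described by the gamma-variate (GV)
function

    f(t) = 0                                             for t <= AT
    f(t) = A * (t - AT)**alpha * exp(-(t - AT) / beta)   for t >  AT

where ``A`` (amplitude) sets the intensity scale, ``alpha`` (dimensionless)
and ``beta`` (seconds) shape the wash-in/wash-out, and ``AT`` is the
contrast arrival time.  The curve is unimodal on ``t > AT`` with its
maximum at ``Tmax = AT + alpha * beta`` and peak value
``A * (alpha*beta)**alpha * exp(-alpha)``.

Only single-pass kinetics are modeled; recirculation and extravascular
leakage are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["GVParams", "TimeGrid", "gv_value", "gv_derived", "sample_curve"]

#: Fraction of peak intensity at which contrast is considered washed out;
#: used by the leave-time (LT) computation.
LEAVE_FRACTION = 0.05


@dataclass(frozen=True)
class GVParams:
    """Parameters of one voxel's gamma-variate transit curve.

    Attributes
    ----------
    amplitude : float
        Non-negative intensity scale ``A``.
    alpha : float
        Dimensionless shape parameter, strictly positive.
    beta : float
        Timescale in seconds, strictly positive.
    arrival_time : float
        Contrast arrival time ``AT`` in seconds, non-negative.
    """

    amplitude: float
    alpha: float
    beta: float
    arrival_time: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"amplitude must be finite and >= 0, got {self.amplitude}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not (np.isfinite(self.arrival_time) and self.arrival_time >= 0):
            raise ValueError(
                f"arrival_time must be finite and >= 0, got {self.arrival_time}"
            )

    @property
    def tmax(self) -> float:
        """Time of maximal signal intensity, ``AT + alpha * beta``."""
        return self.arrival_time + self.alpha * self.beta

    @property
    def peak(self) -> float:
        """Maximal signal intensity, attained at :attr:`tmax`."""
        return float(
            self.amplitude
            * (self.alpha * self.beta) ** self.alpha
            * np.exp(-self.alpha)
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.amplitude, self.alpha, self.beta, self.arrival_time])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "GVParams":
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]))


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition time grid: frame ``k`` is at ``origin + k / frame_rate``.

    Frame indices are 0-based; all times are in seconds.
    """

    n_frames: int
    frame_rate: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if not (np.isfinite(self.frame_rate) and self.frame_rate > 0):
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, strictly increasing."""
        return self.origin + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        """Time of the last frame relative to the origin."""
        return (self.n_frames - 1) / self.frame_rate


def gv_value(params: GVParams, t) -> np.ndarray | float:
    """Evaluate the gamma-variate curve at time(s) ``t`` (seconds).

    Returns 0 for ``t <= arrival_time``; the curve is continuous at the
    arrival time for ``alpha > 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    u = t_arr - params.arrival_time
    out = np.zeros_like(u)
    pos = u > 0
    up = u[pos]
    out[pos] = params.amplitude * up**params.alpha * np.exp(-up / params.beta)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def gv_derived(params: GVParams, leave_fraction: float = LEAVE_FRACTION) -> dict:
    """Derived transit-curve quantities: Tmax, peak, and leave time (LT).

    LT is the earliest post-peak time at which the curve has decayed to
    ``leave_fraction`` of its peak (default 5%), found by bracketed root
    search on the monotone washout limb.
    """
    tmax = params.tmax
    peak = params.peak
    if peak <= 0:
        return {"tmax": tmax, "peak": 0.0, "leave_time": tmax}
    target = leave_fraction * peak

    def f(t: float) -> float:
        return gv_value(params, t) - target

    # Washout is bounded above by exp decay; expand the bracket until crossed.
    hi = tmax + params.beta
    while f(hi) > 0:
        hi = tmax + 2 * (hi - tmax)
    leave_time = brentq(f, tmax, hi, xtol=1e-10)
    return {"tmax": tmax, "peak": peak, "leave_time": float(leave_time)}


def sample_curve(params: GVParams, grid: TimeGrid) -> np.ndarray:
    """Sample the gamma-variate curve on an acquisition grid.

    Returns an array of length ``grid.n_frames`` with
    ``out[k] = gv_value(params, grid.times[k])``.
    """
    return np.asarray(gv_value(params, grid.times), dtype=float).reshape(-1)
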