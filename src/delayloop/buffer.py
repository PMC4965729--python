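"""Bounded sliding-window storage of time-stamped signals.

A biological controller cannot store an unbounded history: the working
assumption throughout the package is that motor commands and sensed states
are retained only over the window ``[t - tau_max, t]``.  `HistoryBuffer`
enforces that bound (older records are evicted on insert) and serves linear
interpolation between stored samples, which is what lets the estimator and
predictor evaluate signals at off-grid lagged times.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Any

import numpy as np

from .errors import DomainError, OrderingError, OutOfWindowError

__all__ = ["HistoryBuffer"]


class HistoryBuffer:
    """Time-ordered record of a signal over the sliding window ``tau_max``.

    Memory is O(window / sample spacing) regardless of simulation length.
    Values may be floats or fixed-shape numpy vectors.
    """

    __slots__ = ("window", "_t", "_v", "_start")

    def __init__(self, window: float):
        window = float(window)
        if not window > 0.0 or not np.isfinite(window):
            raise DomainError(f"window must be a positive finite duration, got {window}")
        self.window = window
        self._t: list[float] = []
        self._v: list[Any] = []
        self._start = 0  # logical head; physical compaction is amortised

    def __len__(self) -> int:
        return len(self._t) - self._start

    @property
    def latest_time(self) -> float:
        if len(self) == 0:
            raise OutOfWindowError("buffer is empty")
        return self._t[-1]

    @property
    def earliest_time(self) -> float:
        if len(self) == 0:
            raise OutOfWindowError("buffer is empty")
        return self._t[self._start]

    def record(self, t: float, value) -> "HistoryBuffer":
        """Store ``value`` at time ``t`` (strictly after the latest record).

        Records with timestamps older than ``t - window`` are evicted.
        Returns ``self`` for chaining.
        """
        t = float(t)
        if len(self) and t <= self._t[-1]:
            raise OrderingError(
                f"timestamps must be strictly increasing: got {t} after {self._t[-1]}"
            )
        self._t.append(t)
        self._v.append(float(value) if np.isscalar(value) else np.asarray(value, dtype=float).copy())
        cutoff = t - self.window
        while self._t[self._start] < cutoff:
            self._start += 1
        if self._start > 64 and self._start * 2 > len(self._t):
            del self._t[: self._start]
            del self._v[: self._start]
            self._start = 0
        return self

    def sample(self, t_query: float):
        """Linearly interpolated value at ``t_query``.

        Exact at stored timestamps.  Queries outside
        ``[earliest_time, latest_time]`` raise `OutOfWindowError` -- in loop
        terms, the hypothesised delay has exceeded the memory capacity and
        open-loop control prevails; callers must handle it.
        """
        if len(self) == 0:
            raise OutOfWindowError("buffer is empty")
        t_query = float(t_query)
        lo, hi = self._t[self._start], self._t[-1]
        if t_query < lo or t_query > hi:
            raise OutOfWindowError(
                f"query t={t_query} outside buffered window [{lo}, {hi}]"
            )
        i = bisect_right(self._t, t_query, lo=self._start) - 1
        if self._t[i] == t_query:
            v = self._v[i]
            return v if np.isscalar(v) else v.copy()
        t0, t1 = self._t[i], self._t[i + 1]
        w = (t_query - t0) / (t1 - t0)
        return self._v[i] + (self._v[i + 1] - self._v[i]) * w

    def segment(self, t0: float, t1: float):
        """Sample times/values covering ``[t0, t1]`` for quadrature.

        Returns ``(times, values)`` arrays: the stored samples strictly
        inside the interval plus interpolated endpoint values, suitable for
        the trapezoidal rule.  ``t0 == t1`` yields a two-point degenerate
        segment whose integral is exactly zero.
        """
        if t1 < t0:
            raise DomainError(f"segment requires t0 <= t1, got [{t0}, {t1}]")
        v0 = self.sample(t0)
        v1 = self.sample(t1)
        i = bisect_right(self._t, float(t0), lo=self._start)
        j = bisect_left(self._t, float(t1), lo=self._start)
        times = [float(t0), *self._t[i:j], float(t1)]
        values = [v0, *self._v[i:j], v1]
        return np.asarray(times), np.asarray(values)
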