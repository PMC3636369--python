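"""Breakpointed time series used for all time-varying parameters.

Values are linear between breakpoints and constant beyond the ends; the
time axis is calendar years CE (negative = BC).
"""

from __future__ import annotations

from typing import Annotated, Any

import numpy as np
from pydantic import BaseModel, BeforeValidator, model_validator


class TimeSeries(BaseModel):
    """Piecewise-linear series ``v(t)`` on strictly increasing breakpoints."""

    t: list[float]
    v: list[float]

    @model_validator(mode="after")
    def _check(self) -> "TimeSeries":
        if len(self.t) == 0:
            raise ValueError("time series must have at least one breakpoint")
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")
        diffs = np.diff(self.t)
        if np.any(diffs <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        return self

    def at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.v))

    def slope_at(self, t: float) -> float:
        """Local derivative dv/dt; zero outside the breakpoint span."""
        ts = self.t
        if len(ts) < 2 or t <= ts[0] or t >= ts[-1]:
            return 0.0
        i = int(np.searchsorted(ts, t, side="right")) - 1
        i = min(max(i, 0), len(ts) - 2)
        return (self.v[i + 1] - self.v[i]) / (ts[i + 1] - ts[i])

    def is_constant_between(self, t0: float, t1: float) -> bool:
        """True if the series does not change on [t0, t1].

        Assumes no interior breakpoints in (t0, t1); callers segment time at
        the union of all breakpoints first.
        """
        return self.at(t0) == self.at(t1)

    @property
    def breakpoints(self) -> list[float]:
        return list(self.t)


def _as_series(value: Any) -> Any:
    if isinstance(value, (int, float)):
        return {"t": [0.0], "v": [float(value)]}
    return value


#: Field type accepting either a full ``{"t": [...], "v": [...]}`` mapping or
#: a bare number (shorthand for a constant).
TimeSeriesLike = Annotated[TimeSeries, BeforeValidator(_as_series)]


def interpolate_parameters(series: TimeSeries, t: float) -> float:
    """Value of a breakpointed series at ``t``.

    Linear between breakpoints, constant beyond the first/last breakpoint;
    a single-breakpoint series is constant everywhere.
    """
    if len(series.t) == 0:
        raise ValueError("empty time series")
    return series.at(t)


def constant(value: float) -> TimeSeries:
    return TimeSeries(t=[0.0], v=[float(value)])


def ramp(t0: float, v0: float, t1: float, v1: float) -> TimeSeries:
    return TimeSeries(t=[t0, t1], v=[v0, v1])
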