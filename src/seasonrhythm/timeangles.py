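"""Calendar-date to annual-angle transforms.

The angular year starts at Jan 1, 00:00 (angle 0) and runs through one full
period (default 365.25 days).  Dates in leap years wrap by at most ~0.3% of a
cycle; no special leap handling is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Default period of the annual cycle, in days.
PERIOD_DAYS = 365.25

TWO_PI = 2.0 * np.pi


def _fractional_day(dates) -> np.ndarray:
    """Return 0-based fractional day-of-year for datetime-like input."""
    try:
        dt = pd.to_datetime(dates, errors="raise")
    except (ValueError, TypeError) as exc:
        raise InputError(f"invalid date(s): {exc}") from exc
    if isinstance(dt, pd.Timestamp):
        dt = pd.DatetimeIndex([dt])
        scalar = True
    else:
        dt = pd.DatetimeIndex(dt)
        scalar = False
    if dt.isna().any():
        raise InputError("missing/invalid dates in input")
    frac = (
        dt.dayofyear.to_numpy(float)
        - 1.0
        + (dt.hour.to_numpy(float) + dt.minute.to_numpy(float) / 60.0
           + dt.second.to_numpy(float) / 3600.0) / 24.0
    )
    return frac[0] if scalar else frac


def date_to_angle(dates, period_days: float = PERIOD_DAYS):
    """Map calendar dates (or 1-based fractional day numbers) to radians.

    theta = 2*pi * ((day_of_year - 1 + fraction_of_day) mod period) / period,
    wrapped to [0, 2*pi).  Numeric input is interpreted as a 1-based fractional
    day (1.0 = Jan 1, 00:00) and may exceed one period (it is wrapped), which
    makes period-shift invariance checks straightforward.

    Parameters
    ----------
    dates : datetime-like, str, number, or array of these
    period_days : length of the annual cycle in days (> 0)
    """
    if period_days <= 0:
        raise InputError(f"period_days must be > 0, got {period_days}")
    arr = np.asarray(dates)
    if arr.dtype.kind in "fiu":
        day0 = arr.astype(float) - 1.0
    else:
        day0 = _fractional_day(dates)
    theta = TWO_PI * (np.mod(day0, period_days)) / period_days
    # guard against round-off pushing exactly to 2*pi
    theta = np.mod(theta, TWO_PI)
    return float(theta) if np.ndim(theta) == 0 else theta


def angle_to_day(theta, period_days: float = PERIOD_DAYS):
    """Inverse of :func:`date_to_angle`: radians -> 1-based fractional day-of-year."""
    theta = np.mod(np.asarray(theta, dtype=float), TWO_PI)
    day = theta / TWO_PI * period_days + 1.0
    return float(day) if np.ndim(day) == 0 else day


def wrap_day(day, period_days: float = PERIOD_DAYS):
    """Wrap a 1-based fractional day-of-year into [1, period+1)."""
    day = np.mod(np.asarray(day, dtype=float) - 1.0, period_days) + 1.0
    return float(day) if np.ndim(day) == 0 else day


def circular_distance_days(day_a, day_b, period_days: float = PERIOD_DAYS):
    """Shortest distance in days between two day-of-year positions on the circle."""
    delta = np.mod(np.asarray(day_a, dtype=float) - np.asarray(day_b, dtype=float),
                   period_days)
    dist = np.minimum(delta, period_days - delta)
    return float(dist) if np.ndim(dist) == 0 else dist
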