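"""Small coercion helpers shared across modules."""

from __future__ import annotations

import datetime as _dt

import pandas as pd

from .errors import ConfigurationError

SECONDS_PER_DAY = 86_400


def to_timedelta(value) -> pd.Timedelta:
    """Coerce a duration-like value to a positive ``pd.Timedelta``.

    Accepts ``pd.Timedelta``, ``datetime.timedelta``, duration strings such
    as ``"5min"`` or ``"1h"``, and bare numbers, which are interpreted as
    MINUTES (the working unit of bin sizes and gap spans).
    """
    if isinstance(value, pd.Timedelta):
        td = value
    elif isinstance(value, _dt.timedelta):
        td = pd.Timedelta(value)
    elif isinstance(value, str):
        td = pd.Timedelta(value)
    elif isinstance(value, (int, float)):
        td = pd.Timedelta(minutes=value)
    else:
        raise ConfigurationError(f"cannot interpret {value!r} as a duration")
    if td <= pd.Timedelta(0):
        raise ConfigurationError(f"duration must be positive, got {td}")
    return td


def to_clock_seconds(value) -> int:
    """Coerce a clock-time-like value to whole seconds since midnight.

    Accepts ``datetime.time``, ``"HH:MM"`` / ``"HH:MM:SS"`` strings, and
    bare integers (seconds since midnight).
    """
    if isinstance(value, _dt.time):
        return value.hour * 3600 + value.minute * 60 + value.second
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) not in (2, 3) or not all(p.isdigit() for p in parts):
            raise ConfigurationError(f"cannot parse clock time {value!r}")
        h, m = int(parts[0]), int(parts[1])
        s = int(parts[2]) if len(parts) == 3 else 0
        if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
            raise ConfigurationError(f"clock time {value!r} out of range")
        return h * 3600 + m * 60 + s
    if isinstance(value, (int,)) and 0 <= value < SECONDS_PER_DAY:
        return int(value)
    raise ConfigurationError(f"cannot interpret {value!r} as a clock time")


def seconds_to_clock(seconds: int) -> _dt.time:
    seconds = int(seconds) % SECONDS_PER_DAY
    return _dt.time(seconds // 3600, (seconds % 3600) // 60, seconds % 60)
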