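"""Reading, writing, and resampling of uniformly sampled single-channel series.

The central type is :class:`RegularSeries`: one numeric channel on a uniform
time grid with an explicit boolean missing mask.  Two on-disk dialects are
supported:

* a generic long-format CSV with a timestamp column and a value column
  (ISO-8601 timestamps, empty cell / ``NaN`` = missing), and
* the smart-meter dialect of the public household electric power consumption
  file (semicolon separator, ``Date;Time;<channels...>`` header, ``d/m/yyyy``
  dates, ``?`` = missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import to_timedelta
from .errors import (
    AlignmentError,
    ConfigurationError,
    DuplicateRecordError,
    FormatError,
    ResampleError,
)

__all__ = [
    "RegularSeries",
    "load_value_csv",
    "load_power_file",
    "resample_to_step",
    "write_value_csv",
]


@dataclass(eq=False)
class RegularSeries:
    """One channel on a uniform time grid with an explicit missing mask.

    ``values`` holds ``NaN`` exactly where ``missing_mask`` is true; every
    non-missing entry is finite.  The grid starts at ``start_time`` and
    advances by ``step`` per slot.
    """

    start_time: pd.Timestamp
    step: pd.Timedelta
    values: np.ndarray
    missing_mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is not None:
            raise AlignmentError("timestamps must be naive local time")
        self.step = to_timedelta(self.step)
        self.values = np.asarray(self.values, dtype=float).copy()
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool).copy()
        if self.values.ndim != 1 or self.missing_mask.ndim != 1:
            raise ValueError("values and missing_mask must be 1-D")
        if len(self.values) != len(self.missing_mask) or len(self.values) < 1:
            raise ValueError("values and missing_mask need equal length >= 1")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-missing entries must be finite")
        self.values[self.missing_mask] = np.nan

    def __len__(self) -> int:
        return len(self.values)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq=self.step)

    @property
    def end_time(self) -> pd.Timestamp:
        """Exclusive end of the last slot's half-open interval."""
        return self.start_time + len(self) * self.step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "value": self.values})

    def equals(self, other: "RegularSeries") -> bool:
        return (
            self.start_time == other.start_time
            and self.step == other.step
            and len(self) == len(other)
            and bool(np.array_equal(self.missing_mask, other.missing_mask))
            and bool(
                np.array_equal(
                    self.values[~self.missing_mask],
                    other.values[~other.missing_mask],
                )
            )
        )


def _series_from_records(
    timestamps: pd.DatetimeIndex,
    values: np.ndarray,
    step: pd.Timedelta,
    label: str,
    line_offset: int = 2,
) -> RegularSeries:
    """Place parsed (timestamp, value) records onto the uniform grid.

    ``line_offset`` is the file line number of the first data record, used in
    error messages.
    """
    bad = pd.isna(timestamps)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + line_offset
        raise FormatError(f"unparseable timestamp at line {line}")
    dup = timestamps.duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + line_offset
        raise DuplicateRecordError(
            f"duplicate timestamp {timestamps[np.flatnonzero(dup)[0]]} at line {line}"
        )
    order = np.argsort(timestamps.values, kind="stable")
    timestamps = timestamps[order]
    values = np.asarray(values, dtype=float)[order]

    start = timestamps[0]
    offsets_ns = (timestamps - start).values.astype("int64")
    step_ns = step.value
    if np.any(offsets_ns % step_ns != 0):
        bad_i = int(np.flatnonzero(offsets_ns % step_ns != 0)[0])
        raise AlignmentError(
            f"timestamp {timestamps[bad_i]} is not aligned to step {step}"
        )
    idx = offsets_ns // step_ns
    n = int(idx[-1]) + 1
    grid = np.full(n, np.nan)
    grid[idx] = values
    grid[~np.isfinite(grid)] = np.nan
    mask = np.isnan(grid)
    return RegularSeries(start, step, grid, mask, label=label)


def _parse_float_column(column: pd.Series) -> np.ndarray:
    """Parse strings to float64 with correctly-rounded ``float()`` so that
    written values round-trip bit-exactly; unparseable or empty -> NaN."""
    out = np.empty(len(column))
    for i, raw in enumerate(column.to_numpy()):
        text = raw.strip()
        try:
            out[i] = float(text) if text else np.nan
        except ValueError:
            out[i] = np.nan
    return out


def load_value_csv(
    path,
    timestamp_column: str = "timestamp",
    value_column: str = "value",
    step="1min",
) -> RegularSeries:
    """Load a generic long-format CSV onto a uniform grid.

    Grid slots absent from the file, and rows whose value cell is empty or
    non-numeric, are flagged missing.
    """
    step = to_timedelta(step)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (timestamp_column, value_column):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not in header {list(df.columns)}"
            )
    ts = pd.to_datetime(df[timestamp_column], errors="coerce", format="ISO8601")
    ts = pd.DatetimeIndex(ts)
    vals = _parse_float_column(df[value_column])
    return _series_from_records(ts, vals, step, label=value_column)


def load_power_file(path, channel: str = "Global_active_power") -> RegularSeries:
    """Load one channel of the semicolon-separated smart-meter file.

    Expects a ``Date;Time;<channels...>`` header with ``d/m/yyyy`` dates and
    ``?`` marking missing values; returns a 1-minute :class:`RegularSeries`.
    """
    try:
        df = pd.read_csv(
            path,
            sep=";",
            dtype=str,
            keep_default_na=False,
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"malformed smart-meter file: {exc}") from exc
    if "Date" not in df.columns or "Time" not in df.columns:
        raise FormatError(
            f"expected 'Date;Time;...' header, got {list(df.columns)}"
        )
    if channel not in df.columns:
        raise ConfigurationError(
            f"unknown channel {channel!r}; available: "
            f"{[c for c in df.columns if c not in ('Date', 'Time')]}"
        )
    ts = pd.to_datetime(
        df["Date"].str.strip() + " " + df["Time"].str.strip(),
        format="%d/%m/%Y %H:%M:%S",
        errors="coerce",
    )
    ts = pd.DatetimeIndex(ts)
    vals = _parse_float_column(df[channel].mask(df[channel].str.strip() == "?", ""))
    return _series_from_records(ts, vals, pd.Timedelta(minutes=1), label=channel)


def resample_to_step(
    series: RegularSeries, target_step, how: str = "mean"
) -> RegularSeries:
    """Aggregate to a coarser grid whose step is a multiple of the source step.

    Each output slot reduces the non-missing source samples in the half-open
    interval ``[slot_start, slot_start + target_step)`` with ``how``
    (``"mean"`` or ``"median"``); a slot with no non-missing source sample is
    flagged missing.
    """
    target_step = to_timedelta(target_step)
    if target_step.value % series.step.value != 0:
        raise ResampleError(
            f"target step {target_step} is not an integer multiple of {series.step}"
        )
    if how not in ("mean", "median"):
        raise ConfigurationError(f"unknown aggregation {how!r}; use mean|median")
    ratio = target_step.value // series.step.value
    if ratio == 1:
        return RegularSeries(
            series.start_time,
            series.step,
            series.values,
            series.missing_mask,
            label=series.label,
        )
    n_out = -(-len(series) // ratio)
    padded = np.full(n_out * ratio, np.nan)
    padded[: len(series)] = series.values
    blocks = padded.reshape(n_out, ratio)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        reduce = np.nanmean if how == "mean" else np.nanmedian
        out = reduce(blocks, axis=1)
    mask = np.all(np.isnan(blocks), axis=1)
    out[mask] = np.nan
    return RegularSeries(series.start_time, target_step, out, mask, label=series.label)


def write_value_csv(series: RegularSeries, path) -> None:
    """Write ``timestamp,value`` CSV; missing slots get an empty value cell.

    Round-trips through :func:`load_value_csv` on grid, values, and mask.
    """
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, na_rep="", columns=["timestamp", "value"])
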