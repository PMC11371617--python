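"""Day x clock-slot view of a regular series, gap masking, and bin windows.

A :class:`DayGrid` arranges a series as a matrix with one row per calendar
day and one column per within-day clock slot, so "impute a day's gap from
the same clock time of other days" becomes a column-wise problem.  A
:class:`GapSpec` names a clock-anchored missing span on one day, and a
:class:`BinWindow` is the column range of configurable width extracted
around the gap.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import SECONDS_PER_DAY, seconds_to_clock, to_clock_seconds, to_timedelta
from .errors import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    PreconditionError,
)
from .timeseries_io import RegularSeries

__all__ = [
    "DayGrid",
    "GapSpec",
    "BinWindow",
    "build_daygrid",
    "gap_slots",
    "mask_gap",
    "make_bin_window",
    "extract_bin_matrix",
    "standard_bin_sizes",
    "grid_to_series",
]

#: Bin-size catalogue in minutes: 1-45 min, then 1-6 h.
_STANDARD_BIN_MINUTES = (1, 2, 3, 4, 5, 10, 15, 30, 45, 60, 120, 180, 240, 300, 360)

#: The whole-day baseline ("entire data") expressed as a bin size.
FULL_DAY = pd.Timedelta(hours=24)


@dataclass(eq=False)
class DayGrid:
    """Matrix view of a series: rows = days, columns = within-day clock slots.

    ``values`` holds NaN exactly where ``missing_mask`` is true.
    ``slot_seconds`` gives each column's clock time as seconds since
    midnight; columns are ``step`` apart.
    """

    day_labels: np.ndarray  # datetime64[D], length D, chronological
    slot_seconds: np.ndarray  # int64, length T
    values: np.ndarray  # D x T float, NaN where missing
    missing_mask: np.ndarray  # D x T bool
    step: pd.Timedelta

    def __post_init__(self) -> None:
        self.day_labels = np.asarray(self.day_labels, dtype="datetime64[D]")
        self.slot_seconds = np.asarray(self.slot_seconds, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float).copy()
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool).copy()
        self.step = to_timedelta(self.step)
        d, t = self.values.shape
        if self.missing_mask.shape != (d, t):
            raise ValueError("values and missing_mask shapes differ")
        if len(self.day_labels) != d or len(self.slot_seconds) != t:
            raise ValueError("label lengths inconsistent with grid shape")
        self.values[self.missing_mask] = np.nan

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_slots(self) -> int:
        return self.values.shape[1]

    @property
    def slot_clock_times(self) -> list[_dt.time]:
        return [seconds_to_clock(s) for s in self.slot_seconds]

    def copy(self) -> "DayGrid":
        return DayGrid(
            self.day_labels.copy(),
            self.slot_seconds.copy(),
            self.values.copy(),
            self.missing_mask.copy(),
            self.step,
        )


@dataclass(frozen=True)
class GapSpec:
    """A clock-anchored missing span on one day of a grid."""

    start_clock: _dt.time
    span: pd.Timedelta
    target_day: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "start_clock", seconds_to_clock(to_clock_seconds(self.start_clock))
        )
        object.__setattr__(self, "span", to_timedelta(self.span))
        start_s = to_clock_seconds(self.start_clock)
        if start_s + self.span.total_seconds() > SECONDS_PER_DAY:
            raise ConfigurationError("gap must lie within a single day")

    @property
    def start_seconds(self) -> int:
        return to_clock_seconds(self.start_clock)


@dataclass(frozen=True)
class BinWindow:
    """Inclusive column range [first_slot, last_slot] of a grid."""

    bin_size: pd.Timedelta
    first_slot: int
    last_slot: int

    @property
    def n_slots(self) -> int:
        return self.last_slot - self.first_slot + 1

    @property
    def slots(self) -> np.ndarray:
        return np.arange(self.first_slot, self.last_slot + 1)


def build_daygrid(
    series: RegularSeries,
    require_complete: bool = True,
    n_days: int | None = None,
    selection_seed: int = 0,
) -> DayGrid:
    """Reshape a series into whole calendar days.

    Only days fully covered by the series' grid are considered.  With
    ``require_complete``, only days with zero missing slots are eligible;
    ``n_days`` of them are then sampled uniformly without replacement with
    ``selection_seed`` and returned in chronological order.  ``n_days=None``
    keeps every eligible day.
    """
    step_s = series.step.value // 10**9
    if series.step.value % 10**9 != 0 or SECONDS_PER_DAY % step_s != 0:
        raise AlignmentError(f"step {series.step} does not divide 24 h evenly")
    midnight_offset = (
        series.start_time - series.start_time.normalize()
    ).value // 10**9
    if midnight_offset % step_s != 0:
        raise AlignmentError("series grid is not phase-aligned with midnight")

    slots_per_day = SECONDS_PER_DAY // step_s
    first_day = (
        series.start_time.normalize()
        if midnight_offset == 0
        else series.start_time.normalize() + pd.Timedelta(days=1)
    )
    start_idx = int((first_day - series.start_time).value // series.step.value)
    n_whole = (len(series) - start_idx) // slots_per_day if start_idx <= len(series) else 0
    if n_whole < 1:
        raise InsufficientDataError("series does not cover a single whole day")

    block = series.values[start_idx : start_idx + n_whole * slots_per_day]
    vals = block.reshape(n_whole, slots_per_day)
    mask = np.isnan(vals)
    day_labels = (
        np.datetime64(first_day.date()) + np.arange(n_whole)
    ).astype("datetime64[D]")

    eligible = np.arange(n_whole)
    if require_complete:
        eligible = eligible[~mask.any(axis=1)]
    if n_days is None:
        if len(eligible) == 0:
            raise InsufficientDataError("no eligible (complete) days in series")
        chosen = eligible
    else:
        if len(eligible) < n_days:
            raise InsufficientDataError(
                f"requested {n_days} days but only {len(eligible)} eligible"
            )
        rng = np.random.default_rng(selection_seed)
        chosen = np.sort(rng.choice(eligible, size=n_days, replace=False))

    slot_seconds = np.arange(slots_per_day, dtype=np.int64) * step_s
    return DayGrid(day_labels[chosen], slot_seconds, vals[chosen], mask[chosen], series.step)


def gap_slots(grid: DayGrid, gap: GapSpec) -> np.ndarray:
    """Contiguous slot indices covering [start_clock, start_clock + span).

    End-exclusive: a 3:22-3:27 gap at 1-min step is exactly the five slots
    3:22 ... 3:26.
    """
    step_s = int(grid.step.total_seconds())
    start_s = gap.start_seconds
    span_s = int(gap.span.total_seconds())
    offset = start_s - int(grid.slot_seconds[0])
    if offset % step_s != 0 or span_s % step_s != 0:
        raise AlignmentError(
            f"gap {gap.start_clock}+{gap.span} is not aligned to step {grid.step}"
        )
    first = offset // step_s
    n = span_s // step_s
    if first < 0 or first + n > grid.n_slots:
        raise AlignmentError("gap lies outside the grid's clock range")
    return np.arange(first, first + n)


def mask_gap(grid: DayGrid, gap: GapSpec) -> tuple[DayGrid, np.ndarray]:
    """Delete the gap cells of the target day, returning (masked copy, truth).

    The deleted true values come back in slot order so the caller can score
    an imputation against them, or restore them to undo the mask.
    """
    slots = gap_slots(grid, gap)
    if not 0 <= gap.target_day < grid.n_days:
        raise PreconditionError(f"target_day {gap.target_day} out of range")
    if grid.missing_mask[gap.target_day, slots].any():
        raise PreconditionError("some gap cells are already missing")
    truth = grid.values[gap.target_day, slots].copy()
    masked = grid.copy()
    masked.missing_mask[gap.target_day, slots] = True
    masked.values[gap.target_day, slots] = np.nan
    return masked, truth


def make_bin_window(grid: DayGrid, gap: GapSpec, bin_size) -> BinWindow:
    """Center a window of ``bin_size`` on the gap.

    The surplus (bin_size - span) is split as evenly as possible with the
    extra slot placed before the gap; a window overhanging a day boundary is
    shifted back inside the day, so the effective width stays bin_size (a
    24-h bin is always the whole day, the no-binning baseline).
    """
    bin_size = to_timedelta(bin_size)
    if bin_size < gap.span:
        raise ConfigurationError(
            f"bin size {bin_size} is smaller than the gap span {gap.span}"
        )
    step_s = int(grid.step.total_seconds())
    if int(bin_size.total_seconds()) % step_s != 0:
        raise AlignmentError(f"bin size {bin_size} not a multiple of step {grid.step}")
    slots = gap_slots(grid, gap)
    n_bin = min(int(bin_size.total_seconds()) // step_s, grid.n_slots)
    surplus = n_bin - len(slots)
    before = (surplus + 1) // 2
    first = int(slots[0]) - before
    last = int(slots[-1]) + (surplus - before)
    if first < 0:  # shift inside the day, preserving the width
        last -= first
        first = 0
    if last > grid.n_slots - 1:
        first -= last - (grid.n_slots - 1)
        last = grid.n_slots - 1
        first = max(first, 0)
    return BinWindow(bin_size=bin_size, first_slot=first, last_slot=last)


def extract_bin_matrix(grid: DayGrid, window: BinWindow) -> DayGrid:
    """Restrict the grid to the window's columns (all days, masks preserved)."""
    if window.first_slot < 0 or window.last_slot >= grid.n_slots:
        raise PreconditionError("window exceeds grid columns")
    sl = slice(window.first_slot, window.last_slot + 1)
    return DayGrid(
        grid.day_labels,
        grid.slot_seconds[sl],
        grid.values[:, sl],
        grid.missing_mask[:, sl],
        grid.step,
    )


def standard_bin_sizes(span) -> list[pd.Timedelta]:
    """The bin-size catalogue {1,2,3,4,5,10,15,30,45 min, 1..6 h}, filtered
    to sizes >= the gap span, ascending."""
    span = to_timedelta(span)
    return [
        pd.Timedelta(minutes=m)
        for m in _STANDARD_BIN_MINUTES
        if pd.Timedelta(minutes=m) >= span
    ]


def grid_to_series(grid: DayGrid, label: str = "") -> RegularSeries:
    """Flatten a grid of consecutive full days back into a RegularSeries."""
    step_s = int(grid.step.total_seconds())
    if grid.n_slots * step_s != SECONDS_PER_DAY:
        raise PreconditionError("grid is not a full-day grid")
    deltas = np.diff(grid.day_labels).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        raise PreconditionError("day labels are not consecutive")
    start = pd.Timestamp(grid.day_labels[0]) + pd.Timedelta(
        seconds=int(grid.slot_seconds[0])
    )
    vals = grid.values.reshape(-1)
    mask = grid.missing_mask.reshape(-1)
    return RegularSeries(start, grid.step, vals, mask, label=label)
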