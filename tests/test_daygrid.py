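import numpy as np
import pandas as pd
import pytest

from binimpute import (
    GapSpec,
    RegularSeries,
    build_daygrid,
    extract_bin_matrix,
    gap_slots,
    grid_to_series,
    make_bin_window,
    mask_gap,
    standard_bin_sizes,
)
from binimpute.errors import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    PreconditionError,
)


def day_series(n_days, step_min=60, missing_days=()):
    """n_days whole days at step_min; chosen days get one missing slot."""
    slots = 1440 // step_min
    vals = np.arange(n_days * slots, dtype=float)
    mask = np.zeros(n_days * slots, dtype=bool)
    for d in missing_days:
        mask[d * slots + 3] = True
    vals[mask] = np.nan
    return RegularSeries("2024-01-01", f"{step_min}min", vals, mask)


class TestBuildDaygrid:
    def test_full_series_shape(self):
        grid = build_daygrid(day_series(30), n_days=30)
        assert grid.values.shape == (30, 24)
        assert not grid.missing_mask.any()

    def test_insufficient_complete_days(self):
        s = day_series(30, missing_days=range(5))
        with pytest.raises(InsufficientDataError, match="25"):
            build_daygrid(s, n_days=28)

    def test_all_complete_days_chronological(self):
        s = day_series(30, missing_days=range(5))
        grid = build_daygrid(s, n_days=25)
        assert grid.n_days == 25
        assert list(grid.day_labels) == sorted(grid.day_labels)
        # the 5 incomplete days were excluded
        excluded = {np.datetime64("2024-01-01") + d for d in range(5)}
        assert excluded.isdisjoint(set(grid.day_labels))

    def test_selection_is_seeded(self):
        s = day_series(30)
        a = build_daygrid(s, n_days=10, selection_seed=42)
        b = build_daygrid(s, n_days=10, selection_seed=42)
        c = build_daygrid(s, n_days=10, selection_seed=43)
        assert np.array_equal(a.day_labels, b.day_labels)
        assert not np.array_equal(a.day_labels, c.day_labels)

    def test_partial_days_excluded(self):
        slots = 24
        vals = np.arange(2 * slots + 5, dtype=float)  # 2 whole days + 5 slots
        s = RegularSeries("2024-01-01", "60min", vals, np.zeros(len(vals), bool))
        grid = build_daygrid(s)
        assert grid.n_days == 2

    def test_step_not_dividing_day_rejected(self):
        s = RegularSeries("2024-01-01", "7min", np.ones(2000), np.zeros(2000, bool))
        with pytest.raises(AlignmentError):
            build_daygrid(s)


class TestGapSlots:
    def test_five_minute_gap_at_0322(self, small_grid):
        # 1-min grid analogue: here the grid fixture is 10-min, so build one
        from helpers import make_grid

        grid = make_grid(np.ones((3, 1440)), step="1min")
        slots = gap_slots(grid, GapSpec("03:22", 5, 0))
        assert list(slots) == [202, 203, 204, 205, 206]

    def test_single_slot_gap(self):
        from helpers import make_grid

        grid = make_grid(np.ones((3, 1440)), step="1min")
        assert list(gap_slots(grid, GapSpec("03:23", 1, 0))) == [203]

    def test_unaligned_span_errors(self):
        from helpers import make_grid

        grid = make_grid(np.ones((3, 1440)), step="1min")
        with pytest.raises(AlignmentError):
            gap_slots(grid, GapSpec("03:22", pd.Timedelta(seconds=90), 0))


class TestMaskGap:
    def test_masks_exactly_gap_cells(self, small_grid):
        gap = GapSpec("03:20", 20, 2)
        masked, truth = mask_gap(small_grid, gap)
        assert truth.shape == (2,)  # 20 min at 10-min step
        assert masked.missing_mask.sum() == 2
        assert not small_grid.missing_mask.any()  # input unchanged

    def test_double_mask_errors(self, small_grid):
        gap = GapSpec("03:20", 20, 0)
        masked, _ = mask_gap(small_grid, gap)
        with pytest.raises(PreconditionError):
            mask_gap(masked, gap)

    def test_other_cells_untouched_and_restorable(self, small_grid):
        gap = GapSpec("03:20", 20, 1)
        masked, truth = mask_gap(small_grid, gap)
        slots = gap_slots(small_grid, gap)
        outside = np.ones_like(small_grid.values, dtype=bool)
        outside[1, slots] = False
        assert np.array_equal(
            masked.values[outside], small_grid.values[outside], equal_nan=True
        )
        masked.values[1, slots] = truth
        masked.missing_mask[1, slots] = False
        assert np.array_equal(masked.values, small_grid.values)
        assert np.array_equal(masked.missing_mask, small_grid.missing_mask)


class TestMakeBinWindow:
    def make_1min(self):
        from helpers import make_grid

        return make_grid(np.ones((3, 1440)), step="1min")

    def test_centered_15min_window(self):
        grid = self.make_1min()
        w = make_bin_window(grid, GapSpec("03:22", 5, 0), 15)
        assert (w.first_slot, w.last_slot) == (197, 211)

    def test_odd_surplus_goes_before(self):
        grid = self.make_1min()
        w = make_bin_window(grid, GapSpec("03:23", 1, 0), 2)
        assert (w.first_slot, w.last_slot) == (202, 203)

    def test_overhang_at_day_start_shifts_inside(self):
        # gap 00:00-00:05, 1-h bin: the window slides to the day start and
        # keeps its full 60-slot width
        grid = self.make_1min()
        w = make_bin_window(grid, GapSpec("00:00", 5, 0), 60)
        assert (w.first_slot, w.last_slot) == (0, 59)

    def test_overhang_at_day_end_shifts_inside(self):
        grid = self.make_1min()
        w = make_bin_window(grid, GapSpec("23:55", 5, 0), 60)
        assert (w.first_slot, w.last_slot) == (1380, 1439)

    def test_bin_smaller_than_span_errors(self):
        grid = self.make_1min()
        with pytest.raises(ConfigurationError):
            make_bin_window(grid, GapSpec("03:22", 5, 0), 4)

    def test_window_contains_gap(self):
        grid = self.make_1min()
        for start, span, size in [("00:01", 1, 60), ("23:50", 5, 360), ("12:00", 15, 15)]:
            gap = GapSpec(start, span, 0)
            w = make_bin_window(grid, gap, size)
            assert set(gap_slots(grid, gap)) <= set(w.slots)
            assert w.n_slots <= size  # never exceeds bin_size in slots


class TestExtractBinMatrix:
    def test_one_hour_window_shape(self):
        from helpers import make_grid

        grid = make_grid(np.random.default_rng(0).normal(size=(30, 1440)), step="1min")
        w = make_bin_window(grid, GapSpec("03:22", 5, 0), 60)
        sub = extract_bin_matrix(grid, w)
        assert sub.values.shape == (30, 60)

    def test_full_day_window_is_identity(self, small_grid):
        w = make_bin_window(small_grid, GapSpec("03:20", 10, 0), "24h")
        sub = extract_bin_matrix(small_grid, w)
        assert np.array_equal(sub.values, small_grid.values)
        assert np.array_equal(sub.slot_seconds, small_grid.slot_seconds)

    def test_masked_cells_stay_masked(self, small_grid):
        gap = GapSpec("03:20", 20, 0)
        masked, _ = mask_gap(small_grid, gap)
        w = make_bin_window(small_grid, gap, 120)
        sub = extract_bin_matrix(masked, w)
        assert sub.missing_mask.sum() == 2


class TestStandardBinSizes:
    def test_one_minute_span_gives_15_sizes(self):
        sizes = standard_bin_sizes(1)
        minutes = [s.total_seconds() / 60 for s in sizes]
        assert minutes == [1, 2, 3, 4, 5, 10, 15, 30, 45, 60, 120, 180, 240, 300, 360]

    def test_five_minute_span_starts_at_five(self):
        assert standard_bin_sizes(5)[0] == pd.Timedelta(minutes=5)
        assert len(standard_bin_sizes(5)) == 11

    def test_fifteen_minute_span_starts_at_fifteen(self):
        assert standard_bin_sizes(15)[0] == pd.Timedelta(minutes=15)


class TestGridToSeries:
    def test_round_trip_through_series(self, small_grid):
        series = grid_to_series(small_grid)
        back = build_daygrid(series, n_days=small_grid.n_days)
        assert np.array_equal(back.values, small_grid.values)
        assert np.array_equal(back.day_labels, small_grid.day_labels)
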