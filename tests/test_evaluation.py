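import datetime as dt

import numpy as np
import pandas as pd
import pytest

from binimpute import (
    EvalRecord,
    GapSpec,
    SweepResult,
    days_improved,
    evaluate_day,
    fluctuation,
    fluctuation_split,
    gap_slots,
    make_bin_window,
    mask_gap,
    rmse,
    sweep,
)
from binimpute.errors import ContractError
from binimpute.imputers import impute
from binimpute.daygrid import extract_bin_matrix
from helpers import make_grid


class TestRmse:
    def test_identical_is_zero(self):
        assert rmse([70.0, 70.0], [70.0, 70.0]) == 0.0

    def test_symmetric_errors(self):
        assert rmse([60.0, 80.0], [70.0, 70.0]) == 10.0

    def test_hand_computed(self):
        assert rmse([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(
            np.sqrt(2.0 / 3.0)
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ContractError):
            rmse([1.0], [1.0, 2.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ContractError):
            rmse([np.nan], [1.0])


class TestEvaluateDay:
    def test_si_equals_cross_day_mean_oracle(self, small_grid):
        gap = GapSpec("03:20", 20, 3)
        rec = evaluate_day(small_grid, gap, "si", 20)
        # independent brute force: cross-day mean of the other days
        slots = gap_slots(small_grid, gap)
        truth = small_grid.values[3, slots]
        others = np.delete(np.arange(small_grid.n_days), 3)
        pred = small_grid.values[np.ix_(others, slots)].mean(axis=0)
        assert rec.rmse == pytest.approx(
            float(np.sqrt(np.mean((truth - pred) ** 2))), rel=1e-12
        )

    def test_day_equal_to_cross_day_mean_gives_zero(self, quiet_grid):
        rec = evaluate_day(quiet_grid, GapSpec("03:20", 10, 0), "si", 60)
        assert rec.rmse == 0.0

    def test_full_day_bin_reproduces_unbinned_baseline(self, small_grid):
        gap = GapSpec("03:20", 20, 1)
        rec = evaluate_day(small_grid, gap, "si", "24h")
        masked, truth = mask_gap(small_grid, gap)
        result = impute(masked, "si")
        slots = gap_slots(small_grid, gap)
        assert rec.rmse == rmse(truth, result.filled[1, slots])

    def test_input_grid_unmodified(self, small_grid):
        before = small_grid.values.copy()
        evaluate_day(small_grid, GapSpec("03:20", 10, 0), "si", 30)
        assert np.array_equal(small_grid.values, before)


class TestSweep:
    def test_record_count(self, small_grid):
        res = sweep(small_grid, "03:20", 20, ["si", "knn"], [20, 40, 60])
        # 6 days x 2 algorithms x (3 bins + baseline)
        assert len(res.records) == 6 * 2 * 4

    def test_composition_matches_evaluate_day(self, small_grid):
        res = sweep(small_grid, "03:20", 20, ["si"], [30], include_baseline=False)
        for d in range(small_grid.n_days):
            rec = evaluate_day(small_grid, GapSpec("03:20", 20, d), "si", 30)
            assert res.records[d].rmse == rec.rmse

    def test_mask_all_days_is_degenerate_for_clock_gaps(self, small_grid):
        # masking the same clock span on every day leaves the gap columns
        # without any observed cell, which no column-based imputer can fill
        from binimpute.errors import DegenerateColumnError

        with pytest.raises(DegenerateColumnError):
            sweep(small_grid, "03:20", 20, ["si"], [60], mask_all_days=True)

    def test_csv_round_trip(self, small_grid, tmp_path):
        res = sweep(small_grid, "03:20", 20, ["si"], [30, 60])
        path = tmp_path / "records.csv"
        res.to_csv(path)
        back = SweepResult.from_csv(path)
        assert back.records == res.records


def _mk_records(binned, baseline, bin_min=60):
    day0 = dt.date(2024, 1, 1)
    recs = []
    for i, (b, f) in enumerate(zip(binned, baseline)):
        day = day0 + dt.timedelta(days=i)
        recs.append(
            EvalRecord(day, "em", pd.Timedelta(minutes=bin_min), dt.time(3, 22),
                       pd.Timedelta(minutes=5), b)
        )
        recs.append(
            EvalRecord(day, "em", pd.Timedelta(hours=24), dt.time(3, 22),
                       pd.Timedelta(minutes=5), f)
        )
    return SweepResult(recs)


class TestDaysImproved:
    def test_strict_comparison(self):
        res = _mk_records([1.0, 2.0, 3.0], [2.0, 2.0, 4.0])
        assert days_improved(res, "em", 60) == 2

    def test_ties_not_counted(self):
        res = _mk_records([1.0, 1.0], [1.0, 1.0])
        assert days_improved(res, "em", 60) == 0

    def test_all_improved(self):
        res = _mk_records([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert days_improved(res, "em", 60) == 3

    def test_missing_records_error(self):
        res = _mk_records([1.0], [2.0])
        with pytest.raises(ContractError):
            days_improved(res, "si", 60)

    def test_anti_monotone_under_rmse_inflation(self):
        binned = [1.0, 2.0, 3.0, 4.0]
        base = [2.5, 2.5, 2.5, 2.5]
        before = days_improved(_mk_records(binned, base), "em", 60)
        after = days_improved(
            _mk_records([b + 1.0 for b in binned], base), "em", 60
        )
        assert after <= before

    def test_summary_table(self, small_grid):
        res = sweep(small_grid, "03:20", 20, ["si"], [30])
        table = res.days_improved_table()
        assert list(table.columns) == [
            "algorithm", "bin_size_minutes", "days_improved", "n_days",
        ]
        assert (table["days_improved"] <= table["n_days"]).all()


class TestFluctuation:
    def test_constant_window_is_zero(self):
        grid = make_grid(np.full((2, 60), 7.0))
        w = make_bin_window(grid, GapSpec("00:30", 2, 0), 10)
        assert fluctuation(grid, w, 0) == 0.0

    def test_two_values_sample_sd(self):
        grid = make_grid(np.array([[60.0, 70.0]]* 2))
        w = make_bin_window(grid, GapSpec("00:00", 1, 0), 2)
        assert fluctuation(grid, w, 0) == pytest.approx(7.0711, abs=1e-4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(60, 4, (1, 60))
        grid = make_grid(vals)
        shifted = make_grid(vals + 100.0)
        w = make_bin_window(grid, GapSpec("00:20", 2, 0), 20)
        assert fluctuation(grid, w, 0) == pytest.approx(fluctuation(shifted, w, 0))

    def test_too_few_observed_errors(self):
        vals = np.array([[1.0, np.nan, np.nan]])
        grid = make_grid(vals)
        w = make_bin_window(grid, GapSpec("00:01", 1, 0), 3)
        with pytest.raises(ContractError):
            fluctuation(grid, w, 0)


class TestFluctuationSplit:
    def test_all_days_improved_empty_group(self, small_grid):
        res = _mk_records([1.0] * 6, [2.0] * 6)
        w = make_bin_window(small_grid, GapSpec("03:20", 10, 0), 60)
        # re-key record days to the grid's labels
        split = fluctuation_split(
            _relabel(res, small_grid), small_grid, w, "em", 60
        )
        assert split.not_improved.size == 0
        assert np.isnan(split.median_not_improved)
        assert split.improved.size == 6

    def test_partition_sizes_sum_to_n_days(self, small_grid):
        res = _relabel(_mk_records([1.0, 3.0, 1.0, 3.0, 1.0, 3.0], [2.0] * 6),
                       small_grid)
        w = make_bin_window(small_grid, GapSpec("03:20", 10, 0), 60)
        split = fluctuation_split(res, small_grid, w, "em", 60)
        assert split.improved.size + split.not_improved.size == small_grid.n_days


def _relabel(res, grid):
    recs = []
    days = [d.astype("datetime64[D]").item() for d in grid.day_labels]
    for i, r in enumerate(res.records):
        recs.append(
            EvalRecord(days[i // 2], r.algorithm, r.bin_size, r.gap_start,
                       r.gap_span, r.rmse)
        )
    return SweepResult(recs, res.baseline_bin)
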