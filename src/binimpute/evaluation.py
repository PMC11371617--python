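"""RMSE scoring, bin-size sweeps, days-improved counts, and fluctuation.

The evaluation protocol masks one day's clock-anchored gap at a time (all
other days fully observed), extracts the bin window around the gap, runs an
imputer on the bin matrix, and scores the filled gap cells against the
deleted truth with RMSE.  The whole-day window (24 h) serves as the
"entire data" baseline that binning is compared against.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import seconds_to_clock, to_clock_seconds, to_timedelta
from .daygrid import (
    FULL_DAY,
    BinWindow,
    DayGrid,
    GapSpec,
    extract_bin_matrix,
    gap_slots,
    make_bin_window,
    mask_gap,
)
from .errors import ContractError
from .imputers import impute

__all__ = [
    "EvalRecord",
    "SweepResult",
    "FluctuationSplit",
    "rmse",
    "evaluate_day",
    "sweep",
    "days_improved",
    "fluctuation",
    "fluctuation_split",
]


def rmse(actual, imputed) -> float:
    """Root mean squared error between two equal-length sequences."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(imputed, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b) or len(a) == 0:
        raise ContractError(
            f"rmse needs equal nonzero lengths, got {a.shape} and {b.shape}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ContractError("rmse inputs must be finite")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class EvalRecord:
    """RMSE of one (day, algorithm, bin size) evaluation."""

    day: _dt.date
    algorithm: str
    bin_size: pd.Timedelta
    gap_start: _dt.time
    gap_span: pd.Timedelta
    rmse: float


@dataclass
class SweepResult:
    """Tidy collection of EvalRecords plus the baseline bin size."""

    records: list[EvalRecord]
    baseline_bin: pd.Timedelta = FULL_DAY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": [r.day.isoformat() for r in self.records],
                "algorithm": [r.algorithm for r in self.records],
                "bin_size_minutes": [
                    r.bin_size.total_seconds() / 60 for r in self.records
                ],
                "gap_start": [r.gap_start.strftime("%H:%M:%S") for r in self.records],
                "gap_span_minutes": [
                    r.gap_span.total_seconds() / 60 for r in self.records
                ],
                "rmse": [r.rmse for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, baseline_bin=FULL_DAY) -> "SweepResult":
        df = pd.read_csv(
            path, dtype={"gap_start": str, "day": str}, float_precision="round_trip"
        )
        records = [
            EvalRecord(
                day=_dt.date.fromisoformat(row.day),
                algorithm=str(row.algorithm),
                bin_size=pd.Timedelta(minutes=float(row.bin_size_minutes)),
                gap_start=seconds_to_clock(to_clock_seconds(row.gap_start)),
                gap_span=pd.Timedelta(minutes=float(row.gap_span_minutes)),
                rmse=float(row.rmse),
            )
            for row in df.itertuples()
        ]
        return cls(records, to_timedelta(baseline_bin))

    def _lookup(self, algorithm: str, bin_size: pd.Timedelta) -> dict[_dt.date, float]:
        return {
            r.day: r.rmse
            for r in self.records
            if r.algorithm == algorithm and r.bin_size == bin_size
        }

    def days_improved_table(self) -> pd.DataFrame:
        """One row per (algorithm, bin size below baseline): days improved."""
        combos = sorted(
            {(r.algorithm, r.bin_size) for r in self.records if r.bin_size != self.baseline_bin}
        )
        n_days = len({r.day for r in self.records})
        rows = [
            {
                "algorithm": alg,
                "bin_size_minutes": b.total_seconds() / 60,
                "days_improved": days_improved(self, alg, b),
                "n_days": n_days,
            }
            for alg, b in combos
        ]
        return pd.DataFrame(rows)


def evaluate_day(
    grid: DayGrid,
    gap: GapSpec,
    algorithm: str,
    bin_size,
    params: dict | None = None,
) -> EvalRecord:
    """Mask the gap on the target day, impute within the bin window, score.

    The input grid is left unmodified; all days other than the target stay
    fully observed during the evaluation.
    """
    bin_size = to_timedelta(bin_size)
    masked, truth = mask_gap(grid, gap)
    window = make_bin_window(grid, gap, bin_size)
    sub = extract_bin_matrix(masked, window)
    result = impute(sub, algorithm, **(params or {}))
    local = gap_slots(grid, gap) - window.first_slot
    predicted = result.filled[gap.target_day, local]
    return EvalRecord(
        day=grid.day_labels[gap.target_day].astype("datetime64[D]").item(),
        algorithm=algorithm,
        bin_size=bin_size,
        gap_start=gap.start_clock,
        gap_span=gap.span,
        rmse=rmse(truth, predicted),
    )


def sweep(
    grid: DayGrid,
    gap_start,
    gap_span,
    algorithms: list[str],
    bin_sizes,
    params: dict | None = None,
    baseline_bin=FULL_DAY,
    include_baseline: bool = True,
    mask_all_days: bool = False,
) -> SweepResult:
    """Evaluate every (day, algorithm, bin size), the gap placed on each day.

    ``params`` maps algorithm name -> keyword arguments for that imputer.
    With ``mask_all_days`` every day's gap is masked simultaneously and each
    imputation is scored on all days at once (non-default protocol).
    """
    params = params or {}
    baseline_bin = to_timedelta(baseline_bin)
    bins = [to_timedelta(b) for b in bin_sizes]
    if include_baseline and baseline_bin not in bins:
        bins = bins + [baseline_bin]

    records: list[EvalRecord] = []
    if mask_all_days:
        masked = grid
        truths = {}
        for d in range(grid.n_days):
            gap = GapSpec(gap_start, gap_span, d)
            masked, truths[d] = mask_gap(masked, gap)
        gap0 = GapSpec(gap_start, gap_span, 0)
        local_parent = gap_slots(grid, gap0)
        for algorithm in algorithms:
            for bin_size in bins:
                window = make_bin_window(grid, gap0, bin_size)
                sub = extract_bin_matrix(masked, window)
                result = impute(sub, algorithm, **params.get(algorithm, {}))
                local = local_parent - window.first_slot
                for d in range(grid.n_days):
                    records.append(
                        EvalRecord(
                            day=grid.day_labels[d].astype("datetime64[D]").item(),
                            algorithm=algorithm,
                            bin_size=bin_size,
                            gap_start=GapSpec(gap_start, gap_span, d).start_clock,
                            gap_span=to_timedelta(gap_span),
                            rmse=rmse(truths[d], result.filled[d, local]),
                        )
                    )
    else:
        for d in range(grid.n_days):
            gap = GapSpec(gap_start, gap_span, d)
            for algorithm in algorithms:
                for bin_size in bins:
                    records.append(
                        evaluate_day(
                            grid, gap, algorithm, bin_size,
                            params.get(algorithm, {}),
                        )
                    )
    return SweepResult(records, baseline_bin)


def days_improved(result: SweepResult, algorithm: str, bin_size) -> int:
    """Days whose binned RMSE is strictly below the 24-h baseline RMSE.

    Ties count as not improved.
    """
    bin_size = to_timedelta(bin_size)
    binned = result._lookup(algorithm, bin_size)
    base = result._lookup(algorithm, result.baseline_bin)
    if set(binned) != set(base) or not binned:
        raise ContractError(
            f"need binned and baseline records for the same days "
            f"(algorithm={algorithm!r}, bin={bin_size})"
        )
    return sum(1 for day, r in binned.items() if r < base[day])


def fluctuation(grid: DayGrid, window: BinWindow, day: int, kind: str = "sd") -> float:
    """Dispersion of one day's observed values within a window.

    ``kind="sd"`` is the sample standard deviation (denominator n-1);
    ``kind="cv"`` divides it by the window mean.
    """
    vals = grid.values[day, window.first_slot : window.last_slot + 1]
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ContractError("fluctuation needs >= 2 observed cells in the window")
    sd = float(np.std(vals, ddof=1))
    if kind == "sd":
        return sd
    if kind == "cv":
        return sd / float(np.mean(vals))
    raise ContractError(f"unknown fluctuation kind {kind!r}")


@dataclass
class FluctuationSplit:
    """Per-day fluctuation values split by strict RMSE improvement."""

    improved: np.ndarray
    not_improved: np.ndarray
    median_improved: float
    median_not_improved: float


def fluctuation_split(
    result: SweepResult,
    grid: DayGrid,
    window: BinWindow,
    algorithm: str,
    bin_size,
    kind: str = "sd",
) -> FluctuationSplit:
    """Partition days by strict improvement and return each group's
    fluctuation sample (box-plot-ready) with group medians.

    An empty group yields an empty sample and a NaN median, not an error.
    """
    bin_size = to_timedelta(bin_size)
    binned = result._lookup(algorithm, bin_size)
    base = result._lookup(algorithm, result.baseline_bin)
    if set(binned) != set(base) or not binned:
        raise ContractError("need matching binned and baseline records")
    day_index = {
        grid.day_labels[d].astype("datetime64[D]").item(): d
        for d in range(grid.n_days)
    }
    improved, not_improved = [], []
    for day in sorted(binned):
        f = fluctuation(grid, window, day_index[day], kind=kind)
        (improved if binned[day] < base[day] else not_improved).append(f)
    improved = np.asarray(improved)
    not_improved = np.asarray(not_improved)
    return FluctuationSplit(
        improved=improved,
        not_improved=not_improved,
        median_improved=float(np.median(improved)) if improved.size else float("nan"),
        median_not_improved=(
            float(np.median(not_improved)) if not_improved.size else float("nan")
        ),
    )
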