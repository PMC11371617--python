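import numpy as np
import pandas as pd

from binimpute import DayGrid


def make_grid(values, step="1min", start="2024-01-01"):
    """Wrap a bare 2-D NaN-coded array into a DayGrid."""
    values = np.asarray(values, dtype=float)
    d, t = values.shape
    step = pd.Timedelta(step)
    day_labels = np.datetime64(start) + np.arange(d)
    slot_seconds = np.arange(t, dtype=np.int64) * int(step.total_seconds())
    return DayGrid(day_labels, slot_seconds, values, np.isnan(values), step)
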