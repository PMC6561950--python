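"""Double-plotted actogram export as a plain numeric grid.

Row ``d`` of the matrix holds day ``d`` followed by day ``d+1`` (per-bin
sums), the conventional double-plotted layout that makes a drifting
free-running rhythm readable as a sloped band.  Rendering is left to any
plotting layer; the grid itself is plain text-friendly.
"""

from __future__ import annotations

import numpy as np

from .series import UniformSeries

__all__ = ["double_plot_matrix"]


def double_plot_matrix(s: UniformSeries, bin_minutes: float = 6.0) -> np.ndarray:
    """Days x (2 * bins-per-day) matrix of per-bin sums, double-plotted.

    Requires at least two complete days; a trailing partial day is dropped.
    Row ``d`` is the concatenation of day ``d`` and day ``d+1``, so the second
    half of each row equals the first half of the next by construction.
    """
    binned = s.rebin_sum(bin_minutes)
    per_day = int(round(24.0 * 60.0 / bin_minutes))
    if abs(per_day * bin_minutes - 1440.0) > 1e-9:
        raise ValueError("bin_minutes must divide 24 hours evenly")
    n_days = binned.n // per_day
    if n_days < 2:
        raise ValueError("need at least two complete days for a double plot")
    grid = binned.values[: n_days * per_day].reshape(n_days, per_day).astype(float)
    return np.hstack([grid[:-1], grid[1:]])
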