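import numpy as np
import pytest

from circakit import UniformSeries


def square_wave_activity(n_days: float, onset_h: float = 18.0, period_h: float = 24.0,
                         step_minutes: float = 6.0, high: float = 10.0,
                         active_h: float = 12.0) -> UniformSeries:
    """Noiseless square-wave activity: ``high`` counts from ``onset_h`` for
    ``active_h`` hours each ``period_h`` cycle, zero otherwise."""
    n = int(round(n_days * 1440.0 / step_minutes))
    t = np.arange(n) * step_minutes / 60.0
    phase = np.mod(t - onset_h, period_h)
    vals = np.where(phase < active_h, high, 0.0)
    return UniformSeries(0.0, step_minutes, vals)


@pytest.fixture
def square_wave():
    return square_wave_activity
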