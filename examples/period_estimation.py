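"""Free-running period estimation with the chi-square periodogram.

Simulates 40-day constant-darkness activity records for a wild-type-like
(tau = 23.71 h) and a short-period mutant-like (tau = 23.50 h) animal, then
recovers each period from the counts alone.  The printed estimates should
match the generating periods to the 0.1 h resolution of the period grid.
"""

import numpy as np

from circakit import ActivitySimParams, LightSchedule, estimate_period, generate_activity

for label, tau, seed in [("wild-type-like", 23.71, 1), ("mutant-like", 23.50, 2)]:
    params = ActivitySimParams(intrinsic_period_h=tau, mesor=5.0, amplitude=0.8,
                               duration_days=43.0, seed=seed)
    record = generate_activity(params, LightSchedule.dd(43))
    est = estimate_period(record)  # 40-day window starting day 3, 20-28 h search
    print(f"{label}: true tau = {tau:.2f} h, periodogram estimate = {est:.2f} h")
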