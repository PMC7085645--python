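"""Batch telemetry analytics: speed, production, percentages, stop flags.

Builds a synthetic telemetry log — one record per 1000 pockets at chain
speed, with a drifting boat rate (a slowly misaligning straightening brush)
and one half-hour machine stop — then computes the per-batch statistics an
operator would watch.
"""

from datetime import datetime, timedelta

import numpy as np

from olivesort.diagnostics import (
    BatchRecord, compute_stats, throughput_from_packet_time,
)

rng = np.random.default_rng(0)
t = datetime(2026, 9, 23, 8, 0)
records = []
for i in range(12):
    t += timedelta(seconds=24 if i != 8 else 1800)  # batch 8 follows a stop
    boat = 8 + i  # drifting fault: boats climb batch over batch
    empty = int(rng.integers(20, 60))
    double = int(rng.integers(0, 6))
    counts = {"normal": 1000 - boat - empty - double, "boat": boat,
              "empty": empty, "double": double}
    records.append(BatchRecord(t, counts))

stats = compute_stats(records)
cols = ["speed", "production", "pct_boat", "acc_boat", "acc_double", "stop"]
print(stats[cols].round(2).to_string())
print(f"\nflagged machine stops: {int(stats['stop'].sum())}")
img_s, olv_min = throughput_from_packet_time(22.41)
print(f"single 258-byte packet every 22.41 ms -> {img_s:.1f} images/s "
      f"({olv_min:.1f} olives/min)")
# speed is pockets/min; production excludes empty pockets; the rising
# acc_boat slope is the drifting-brush signature an operator reacts to.
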