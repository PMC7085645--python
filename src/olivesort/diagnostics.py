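"""Telemetry analytics for the pitting machine: per-1000-pocket batch stats.

The sorting rig emits one record per 1000 pockets: a timestamp and the
count of each category (normal, boat, empty, double, small_part, anomaly)
in that batch.  From a time-ordered log this module derives, per batch:

* speed — pockets per minute (batch_size / elapsed × 60);
* production — olives per minute, i.e. excluding empty pockets;
* category percentages, both over all pockets and over non-empty pockets
  (the machine's "production"); the two readings are reported side by side;
* accumulated (prefix-sum) category series, whose slopes expose drifting
  machine faults — a misaligned straightening brush shows up as a growing
  boat slope, a misadjusted feed plate as growing doubles;
* machine-stop flags: an inter-batch gap far above the typical cadence
  (default 5× the median elapsed) marks a stop.

Also included is the packet-timing arithmetic used to size the chip-to-PC
link: an image classified every t ms corresponds to 1000/t images per
second and 60000/t olives per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "BatchRecord",
    "LogFormatError",
    "compute_stats",
    "throughput_from_packet_time",
    "read_log",
    "write_log",
    "plot_accumulated",
    "plot_instantaneous",
]

CATEGORIES = ("normal", "boat", "empty", "double", "small_part", "anomaly")
DEFAULT_BATCH_SIZE = 1000


class LogFormatError(ValueError):
    """Malformed telemetry log; message carries the offending line."""


@dataclass(frozen=True)
class BatchRecord:
    """Counts for one batch of pockets (nominally 1000) at one timestamp."""

    timestamp: datetime
    counts: dict[str, int]
    batch_size: int = DEFAULT_BATCH_SIZE

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if sum(self.counts.values()) != self.batch_size:
            raise ValueError(
                f"counts sum to {sum(self.counts.values())}, "
                f"expected batch_size {self.batch_size}"
            )

    def count(self, category: str) -> int:
        return self.counts.get(category, 0)


def compute_stats(
    records: Sequence[BatchRecord],
    stop_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Per-batch statistics table from a time-ordered record sequence.

    Columns: ``speed`` and ``production`` in units per minute (NaN for the
    first record, which has no elapsed interval), ``pct_<cat>`` over the
    batch, ``pct_nonempty_<cat>`` over non-empty pockets, ``acc_<cat>``
    prefix sums, ``elapsed`` seconds, and a boolean ``stop`` flag for gaps
    above ``stop_threshold`` seconds (default 5× the median elapsed).
    """
    if not records:
        return pd.DataFrame()
    ts = [r.timestamp for r in records]
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            raise ValueError(
                f"timestamps not strictly increasing at record {i}: "
                f"{ts[i - 1]} -> {ts[i]}"
            )
    elapsed = np.array(
        [np.nan] + [(ts[i] - ts[i - 1]).total_seconds() for i in range(1, len(ts))]
    )
    df = pd.DataFrame({"timestamp": ts, "elapsed": elapsed})
    df["batch_size"] = [r.batch_size for r in records]
    for c in CATEGORIES:
        df[c] = [r.count(c) for r in records]

    df["speed"] = df["batch_size"] / df["elapsed"] * 60.0
    nonempty = df["batch_size"] - df["empty"]
    df["production"] = nonempty / df["elapsed"] * 60.0
    for c in CATEGORIES:
        df[f"pct_{c}"] = df[c] / df["batch_size"] * 100.0
        df[f"pct_nonempty_{c}"] = np.where(
            nonempty > 0, df[c] / nonempty.replace(0, np.nan) * 100.0, 0.0
        )
        df[f"acc_{c}"] = df[c].cumsum()

    if stop_threshold is None:
        med = np.nanmedian(elapsed) if len(records) > 1 else np.nan
        stop_threshold = 5.0 * med if np.isfinite(med) else np.inf
    df["stop"] = df["elapsed"] > stop_threshold
    return df


def throughput_from_packet_time(ms_per_image: float) -> tuple[float, float]:
    """(images/s, olives/min) from the per-image communication time in ms."""
    if ms_per_image <= 0:
        raise ValueError(f"ms_per_image must be positive, got {ms_per_image}")
    images_per_s = 1000.0 / ms_per_image
    return images_per_s, images_per_s * 60.0


# ------------------------------------------------------------------ log I/O

_HEADER = ["timestamp", "batch_size", *CATEGORIES]


def write_log(records: Sequence[BatchRecord], path: str | Path) -> None:
    """Write records as CSV (ISO-8601 timestamps, one count column per category)."""
    rows = [
        {
            "timestamp": r.timestamp.isoformat(),
            "batch_size": r.batch_size,
            **{c: r.count(c) for c in CATEGORIES},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_HEADER).to_csv(path, index=False)


def read_log(path: str | Path) -> list[BatchRecord]:
    """Read and validate a telemetry CSV; errors carry the 1-based line number."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise LogFormatError(f"{path}: empty file (expected header {_HEADER})")
    missing = [c for c in _HEADER if c not in df.columns]
    if missing:
        raise LogFormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            ts = datetime.fromisoformat(str(row["timestamp"]))
        except ValueError as e:
            raise LogFormatError(f"{path}:{line}: bad timestamp: {e}") from e
        try:
            rec = BatchRecord(
                timestamp=ts,
                batch_size=int(row["batch_size"]),
                counts={c: int(row[c]) for c in CATEGORIES},
            )
        except (ValueError, TypeError) as e:
            raise LogFormatError(f"{path}:{line}: {e}") from e
        records.append(rec)
    return records


# ------------------------------------------------------------------ plotting

def plot_accumulated(stats: pd.DataFrame, categories: Sequence[str] = ("boat", "double"),
                     ax=None):
    """Accumulated category counts over time (one line per category)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in categories:
        ax.plot(stats["timestamp"], stats[f"acc_{c}"], label=c)
    ax.set_xlabel("time")
    ax.set_ylabel("accumulated count")
    ax.legend()
    return ax


def plot_instantaneous(stats: pd.DataFrame,
                       columns: Sequence[str] = ("speed", "production"), ax=None):
    """Per-batch series (speed, production or raw counts) over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in columns:
        ax.plot(stats["timestamp"], stats[c], label=c)
    ax.set_xlabel("time")
    ax.legend()
    return ax
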