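"""Categorical interval encoding of multi-unit spike trains.

Turns a recording plus a designated target unit into a flat table of 50 ms
intervals suitable for a categorical classifier:

* a **positive interval** is the 50 ms window that precedes each target
  spike; its timestamp is the spike time and its class bit is 1;
* **negative intervals** tile the remaining recording time in 50 ms blocks
  (timestamp at the block end, class bit 0), never overlapping a positive
  window.

Within each interval every predictor unit's firing is summarized as a code
over ``A..E``: one letter per spike, ``A`` for an offset within 10 ms of the
timestamp, ``B`` for 10-20 ms, ... ``E`` for 40-50 ms; multiple spikes in
one 10 ms subinterval repeat the letter ("BBD" = two spikes 10-20 ms back
and one 30-40 ms back), and ``"0"`` means the unit was silent in the window.

Conventions (where a choice had to be made): offsets are measured as
``timestamp - spike_time`` with half-open bins ``[10k, 10(k+1))`` ms, so a
spike exactly at the timestamp codes ``A`` and one exactly 50 ms before is
outside the window; negative blocks are tiled forward from the start of
each gap between positive windows and a terminal remainder shorter than the
window is discarded; target spikes earlier than one full window into the
recording yield no positive interval; and the target's own history is not a
predictor column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netsim import SpikeTrainSet

__all__ = [
    "IntervalTable",
    "encode_code",
    "extract_intervals",
    "read_spike_csv",
    "write_spike_csv",
    "read_interval_csv",
    "write_interval_csv",
]

logger = logging.getLogger(__name__)

_LETTERS = "ABCDE"
CLASS_COLUMN = "R"
TIME_COLUMN = "timestamp_s"


@dataclass
class IntervalTable:
    """Rows = 50 ms intervals; columns = per-unit codes; class = target fired.

    ``data`` is a DataFrame with columns ``timestamp_s``, one string-code
    column per predictor unit (target excluded), and the class column ``R``.
    """

    data: pd.DataFrame
    units: list[str]
    target: str
    window_ms: float = 50.0
    bin_ms: float = 10.0

    def __post_init__(self) -> None:
        expected = [TIME_COLUMN, *self.units, CLASS_COLUMN]
        if list(self.data.columns) != expected:
            raise ValueError(f"interval table columns must be {expected}")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_positive(self) -> int:
        return int((self.data[CLASS_COLUMN] == 1).sum())

    @property
    def n_negative(self) -> int:
        return self.n_rows - self.n_positive

    @property
    def y(self) -> np.ndarray:
        return self.data[CLASS_COLUMN].to_numpy(dtype=np.int8)

    def codes(self, unit: str) -> np.ndarray:
        return self.data[unit].to_numpy(dtype=object)


def encode_code(offsets_ms, bin_ms: float = 10.0, window_ms: float = 50.0) -> str:
    """Encode spike offsets (ms before the timestamp) as an ``A..E`` code.

    One letter per spike, letter ``k`` for an offset in ``[k*bin, (k+1)*bin)``
    ms, letters sorted alphabetically; ``"0"`` for no spikes.
    """
    offsets = np.asarray(list(offsets_ms), dtype=float)
    if offsets.size == 0:
        return "0"
    if np.any(offsets < 0) or np.any(offsets >= window_ms):
        bad = offsets[(offsets < 0) | (offsets >= window_ms)]
        raise ValueError(f"offsets outside [0, {window_ms}) ms: {bad.tolist()}")
    bins = np.floor(offsets / bin_ms).astype(int)
    return "".join(sorted(_LETTERS[b] for b in bins))


def _codes_for_unit(
    spike_times: np.ndarray, timestamps: np.ndarray, window_s: float, bin_s: float, n_bins: int
) -> np.ndarray:
    """Vectorized per-row code strings for one predictor unit.

    A spike contributes to the interval at timestamp ``t`` when its offset
    ``t - spike`` lies in ``[0, window)``, i.e. the spike lies in
    ``(t - window, t]``; bin ``k`` collects spikes in ``(t-(k+1)*bin, t-k*bin]``.
    """
    n = timestamps.size
    # cumulative spike counts at the 6 bin edges (right-inclusive)
    edges = np.empty((n_bins + 1, n), dtype=np.int64)
    for k in range(n_bins + 1):
        edges[k] = np.searchsorted(spike_times, timestamps - k * bin_s, side="right")
    counts = edges[:-1] - edges[1:]          # (n_bins, n)
    total = counts.sum(axis=0)
    out = np.full(n, "0", dtype=object)
    cache: dict[bytes, str] = {}
    for i in np.nonzero(total)[0]:
        key = counts[:, i].tobytes()
        code = cache.get(key)
        if code is None:
            code = "".join(_LETTERS[k] * int(counts[k, i]) for k in range(n_bins))
            cache[key] = code
        out[i] = code
    return out


def extract_intervals(
    spikes: SpikeTrainSet,
    target: str,
    window_ms: float = 50.0,
    bin_ms: float = 10.0,
) -> IntervalTable:
    """Build the categorical interval table for ``target`` from a recording."""
    if target not in spikes.trains:
        raise KeyError(f"target unit {target!r} not present in the recording")
    if window_ms % bin_ms != 0:
        raise ValueError("window_ms must be divisible by bin_ms")
    n_bins = int(round(window_ms / bin_ms))
    window_s = window_ms / 1000.0
    bin_s = bin_ms / 1000.0
    duration = spikes.duration
    if duration < window_s:
        warnings.warn("recording shorter than one window; empty interval table")
        units = [u for u in spikes.units if u != target]
        empty = pd.DataFrame(
            {TIME_COLUMN: pd.Series(dtype=float)}
            | {u: pd.Series(dtype=object) for u in units}
            | {CLASS_COLUMN: pd.Series(dtype=np.int8)}
        )
        return IntervalTable(empty, units, target, window_ms, bin_ms)

    target_spikes = spikes.trains[target]
    pos_ts = target_spikes[target_spikes >= window_s]
    n_dropped = target_spikes.size - pos_ts.size
    if n_dropped:
        logger.info("dropped %d target spikes earlier than one window", n_dropped)

    # union of positive windows [t - window, t)
    neg_ts: list[float] = []
    gap_start = 0.0
    starts = pos_ts - window_s
    merged: list[tuple[float, float]] = []
    for s0, e0 in zip(starts, pos_ts):
        if merged and s0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e0))
        else:
            merged.append((s0, e0))
    # tile every gap (outside positive windows) forward in window-sized blocks
    for s0, e0 in merged + [(duration, duration)]:
        n_blocks = int(np.floor((s0 - gap_start) / window_s + 1e-9))
        for k in range(1, n_blocks + 1):
            neg_ts.append(gap_start + k * window_s)
        gap_start = e0
    neg_ts_arr = np.asarray(neg_ts)

    timestamps = np.concatenate([pos_ts, neg_ts_arr])
    y = np.concatenate(
        [np.ones(pos_ts.size, dtype=np.int8), np.zeros(neg_ts_arr.size, dtype=np.int8)]
    )
    order = np.argsort(timestamps, kind="stable")
    timestamps, y = timestamps[order], y[order]

    units = [u for u in spikes.units if u != target]
    cols: dict[str, object] = {TIME_COLUMN: timestamps}
    for u in units:
        cols[u] = _codes_for_unit(spikes.trains[u], timestamps, window_s, bin_s, n_bins)
    cols[CLASS_COLUMN] = y
    return IntervalTable(pd.DataFrame(cols), units, target, window_ms, bin_ms)


# --------------------------------------------------------------------------
# CSV plumbing
# --------------------------------------------------------------------------

SPIKE_HEADER = ("unit_id", "spike_time_s")


def read_spike_csv(path, duration: float | None = None) -> SpikeTrainSet:
    """Read a long-format spike CSV (``unit_id,spike_time_s``).

    Unsorted times are accepted and sorted with a logged warning; duplicate
    or non-numeric times raise with the offending line number.
    """
    df = pd.read_csv(path, dtype={0: str})
    if tuple(df.columns[:2]) != SPIKE_HEADER:
        raise ValueError(
            f"{path}: malformed header {tuple(df.columns)!r}, expected {SPIKE_HEADER}"
        )
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = np.nonzero(times.isna().to_numpy())[0]
    if bad.size:
        raise ValueError(f"{path}: non-numeric spike time on line {bad[0] + 2}")
    trains: dict[str, np.ndarray] = {}
    for uid, grp in df.assign(spike_time_s=times).groupby("unit_id", sort=False):
        t = grp["spike_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            logger.warning("unit %s: spike times unsorted; sorting", uid)
            t = np.sort(t)
        dup = np.nonzero(np.diff(t) == 0)[0]
        if dup.size:
            line = grp.index[dup[0] + 1] + 2
            raise ValueError(f"{path}: duplicate spike time for unit {uid} on line {line}")
        trains[str(uid)] = t
    if duration is None:
        duration = float(max((t[-1] for t in trains.values() if t.size), default=0.0)) + 1e-3
    return SpikeTrainSet(duration=duration, trains=trains)


def write_spike_csv(spikes: SpikeTrainSet, path) -> None:
    """Write a recording as long-format CSV with millisecond-or-better times."""
    frames = [
        pd.DataFrame({"unit_id": uid, "spike_time_s": t}) for uid, t in spikes.trains.items()
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(SPIKE_HEADER))
    )
    out.to_csv(path, index=False, float_format="%.6f")


def write_interval_csv(table: IntervalTable, path) -> None:
    table.data.to_csv(path, index=False, float_format="%.6f")


def read_interval_csv(path, target: str = "target") -> IntervalTable:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != TIME_COLUMN or df.columns[-1] != CLASS_COLUMN:
        raise ValueError(
            f"{path}: interval CSV must start with {TIME_COLUMN!r} and end with {CLASS_COLUMN!r}"
        )
    units = list(df.columns[1:-1])
    df[TIME_COLUMN] = pd.to_numeric(df[TIME_COLUMN])
    df[CLASS_COLUMN] = df[CLASS_COLUMN].astype(np.int8)
    for u in units:
        df[u] = df[u].astype(object)
    return IntervalTable(df, units, target)
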