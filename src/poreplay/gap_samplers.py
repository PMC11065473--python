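"""Gap samplers: inter-read idle-time models fitted from sequencing summaries.

After every read a channel consults a :class:`GapSampler` to decide what
happens next: a short gap (pore loading), a long gap (temporary blockage),
or permanent channel death.  Four strategies are provided:

* constant/random gaps for prototyping and peak-throughput stress tests,
* replication of an existing run's exact per-channel gap sequence,
* windowed aggregation of all channels' gaps resampled in fixed time
  windows, and
* the recommended per-channel rolling window, which first assigns each
  simulated channel a source channel and then resamples that channel's
  gaps from a sliding time window around the current simulated time.

All strategies are fitted from an ONT sequencing-summary TSV via
:func:`read_seq_summary` and :func:`extract_gap_series`.
"""

from __future__ import annotations

import json
import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .channel_engine import ChannelStats

logger = logging.getLogger(__name__)

__all__ = [
    "GapSpec",
    "Gap",
    "ChannelGapSeries",
    "GapSampler",
    "ConstantGapSampler",
    "ReplicationGapSampler",
    "WindowedAggregateSampler",
    "RollingWindowPerChannelSampler",
    "read_seq_summary",
    "extract_gap_series",
    "classify_gaps",
    "make_constant_gap_sampler",
    "make_replication_sampler",
    "make_windowed_aggregate_sampler",
    "make_rolling_window_per_channel_sampler",
    "sample_gap",
    "save_gap_series",
    "load_gap_series",
]

DEFAULT_LONG_GAP_THRESHOLD = 10.0  # seconds
DEFAULT_ROLLING_WINDOW = 600.0  # seconds

#: Required sequencing-summary columns (ONT vocabulary).
REQUIRED_SUMMARY_COLUMNS = (
    "read_id",
    "channel",
    "start_time",
    "duration",
    "sequence_length_template",
)


@dataclass(frozen=True)
class GapSpec:
    """A sampled gap decision: ``short``/``long`` with a duration, or
    ``inactive`` (permanent channel death, no duration)."""

    kind: str  # "short" | "long" | "inactive"
    duration: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("short", "long", "inactive"):
            raise ValueError(f"unknown gap kind {self.kind!r}")
        if self.kind == "inactive":
            if self.duration is not None:
                raise ValueError("inactive gaps carry no duration")
        else:
            if self.duration is None or self.duration < 0:
                raise ValueError("gap duration must be >= 0")


@dataclass(frozen=True)
class Gap:
    """One observed inter-read gap: start time on the run timeline and length."""

    t_at: float
    duration: float


@dataclass
class ChannelGapSeries:
    """Per-channel gap structure extracted from a sequencing summary."""

    channel: int
    gaps: List[Gap] = field(default_factory=list)
    first_read_delay: float = 0.0
    channel_end_time: float = 0.0
    n_clamped: int = 0  # overlapping records clamped to a zero gap

    @property
    def durations(self) -> np.ndarray:
        return np.array([g.duration for g in self.gaps], dtype=float)


def read_seq_summary(path: Union[str, Path]) -> pd.DataFrame:
    """Read an ONT sequencing-summary TSV (plain or gzip).

    Raises ``ValueError`` naming any missing required column; unknown
    columns are ignored.
    """
    # round_trip float parsing: fitted gap durations must reproduce the
    # written timeline bit-for-bit
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sequencing summary missing required columns: {missing}")
    return df


def extract_gap_series(
    records: Union[pd.DataFrame, Sequence[dict]],
) -> Dict[int, ChannelGapSeries]:
    """Reconstruct per-channel gap series from summary records.

    Per channel the records are sorted by start time; the gap after read *i*
    is ``start_{i+1} - (start_i + duration_i)``, clamped to zero (with a
    counted warning) when basecaller artifacts make records overlap.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    if len(records) == 0:
        raise ValueError("no summary records given")
    missing = [c for c in ("channel", "start_time", "duration") if c not in records]
    if missing:
        raise ValueError(f"summary records missing required columns: {missing}")
    out: Dict[int, ChannelGapSeries] = {}
    for channel, grp in records.groupby("channel"):
        grp = grp.sort_values("start_time")
        starts = grp["start_time"].to_numpy(dtype=float)
        durs = grp["duration"].to_numpy(dtype=float)
        ends = starts + durs
        series = ChannelGapSeries(
            channel=int(channel),
            first_read_delay=float(starts[0]),
            channel_end_time=float(ends.max()),
        )
        for i in range(len(starts) - 1):
            gap = starts[i + 1] - ends[i]
            if gap < 0:
                series.n_clamped += 1
                gap = 0.0
            series.gaps.append(Gap(t_at=float(ends[i]), duration=float(gap)))
        if series.n_clamped:
            logger.warning(
                "channel %d: clamped %d overlapping records to zero gaps",
                series.channel,
                series.n_clamped,
            )
        out[series.channel] = series
    return out


def classify_gaps(
    series: ChannelGapSeries,
    long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
) -> Tuple[List[Gap], List[Gap]]:
    """Partition a channel's gaps into (short, long) by duration threshold.

    A gap exactly at the threshold counts as long.
    """
    if long_gap_threshold <= 0:
        raise ValueError("long_gap_threshold must be > 0")
    short = [g for g in series.gaps if g.duration < long_gap_threshold]
    long_ = [g for g in series.gaps if g.duration >= long_gap_threshold]
    return short, long_


class GapSampler(ABC):
    """Decides the gap after each read, given the channel's live statistics.

    One sampler instance serves all channels; the per-channel key is
    ``stats.channel``.  Given identical seed and call sequence the output
    sequence is identical.
    """

    @abstractmethod
    def sample(self, stats: "ChannelStats") -> GapSpec:
        """Draw the gap that follows the read just finished on ``stats.channel``."""

    def initial_delay(self, stats: "ChannelStats") -> GapSpec:
        """Delay before a channel's first read.  Default: one ordinary draw."""
        return self.sample(stats)


def sample_gap(sampler: GapSampler, stats: "ChannelStats") -> GapSpec:
    """Draw one gap, refusing to sample for a dead channel."""
    if not stats.channel_alive:
        raise ValueError(f"channel {stats.channel} is inactive")
    return sampler.sample(stats)


class ConstantGapSampler(GapSampler):
    """Fixed short gaps, optionally a fixed long gap every *n* reads.

    ``short_gap=0`` produces back-to-back reads — the peak-throughput
    stress case.  Never emits ``inactive``.
    """

    def __init__(
        self,
        short_gap: float,
        long_gap: Optional[float] = None,
        long_gap_every_n_reads: Optional[int] = None,
    ):
        if short_gap < 0:
            raise ValueError("short_gap must be >= 0")
        if long_gap_every_n_reads is not None and long_gap_every_n_reads < 1:
            raise ValueError("long_gap_every_n_reads must be >= 1")
        self.short_gap = float(short_gap)
        self.long_gap = None if long_gap is None else float(long_gap)
        self.long_gap_every_n_reads = long_gap_every_n_reads
        self._draws: Dict[int, int] = {}

    def sample(self, stats) -> GapSpec:
        n = self._draws.get(stats.channel, 0) + 1
        self._draws[stats.channel] = n
        if (
            self.long_gap is not None
            and self.long_gap_every_n_reads is not None
            and n % self.long_gap_every_n_reads == 0
        ):
            return GapSpec("long", self.long_gap)
        return GapSpec("short", self.short_gap)

    def initial_delay(self, stats) -> GapSpec:
        # one plain short gap; does not advance the long-gap counter
        return GapSpec("short", self.short_gap)


def _assign_source_channels(
    source_channels: Sequence[int], n_channels: int, rng: np.random.Generator
) -> List[int]:
    """Map simulated channels 1..n to source channels.

    Up to ``len(source_channels)`` simulated channels reuse the sources by
    index; surplus channels draw a source uniformly with replacement.
    """
    src = list(source_channels)
    assignment = src[:n_channels]
    while len(assignment) < n_channels:
        assignment.append(src[int(rng.integers(len(src)))])
    return assignment


class ReplicationGapSampler(GapSampler):
    """Replays a source run's per-channel gap sequence verbatim.

    Once a simulated channel has consumed its source channel's gaps, or the
    simulated time passes the source channel's last activity, the channel
    is declared inactive.
    """

    def __init__(
        self,
        series_by_channel: Dict[int, ChannelGapSeries],
        n_channels: int,
        seed: Optional[int] = None,
        long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
    ):
        if not series_by_channel:
            raise ValueError("no source channels given")
        rng = np.random.default_rng(seed)
        self.series_by_channel = series_by_channel
        self.long_gap_threshold = long_gap_threshold
        ordered = [series_by_channel[c] for c in sorted(series_by_channel)]
        assignment = _assign_source_channels(
            list(range(len(ordered))), n_channels, rng
        )
        self._source: Dict[int, ChannelGapSeries] = {
            ch + 1: ordered[src] for ch, src in enumerate(assignment)
        }
        self._pos: Dict[int, int] = {ch + 1: 0 for ch in range(n_channels)}

    def _classify(self, duration: float) -> str:
        return "long" if duration >= self.long_gap_threshold else "short"

    def sample(self, stats) -> GapSpec:
        src = self._source[stats.channel]
        pos = self._pos[stats.channel]
        if pos >= len(src.gaps) or stats.t_now > src.channel_end_time:
            return GapSpec("inactive")
        self._pos[stats.channel] = pos + 1
        dur = src.gaps[pos].duration
        return GapSpec(self._classify(dur), dur)

    def initial_delay(self, stats) -> GapSpec:
        src = self._source[stats.channel]
        return GapSpec("short", src.first_read_delay)


class WindowedAggregateSampler(GapSampler):
    """Pools every channel's gaps into fixed time windows and resamples.

    A draw at simulated time *t* resamples (uniformly, with replacement)
    from the pool of window ``floor(t / window)``; an empty window falls
    back to the nearest earlier non-empty window, then to the global pool.
    Emitted durations are always elements of the source gap multiset.
    """

    def __init__(
        self,
        all_series: Dict[int, ChannelGapSeries],
        window: float,
        seed: Optional[int] = None,
        long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
    ):
        if window <= 0:
            raise ValueError("window must be > 0")
        gaps = [g for s in all_series.values() for g in s.gaps]
        if not gaps:
            raise ValueError("no gaps in any source channel")
        self.window = float(window)
        self.long_gap_threshold = long_gap_threshold
        self._rng = np.random.default_rng(seed)
        self._pools: Dict[int, np.ndarray] = {}
        by_window: Dict[int, List[float]] = {}
        for g in gaps:
            by_window.setdefault(int(g.t_at // window), []).append(g.duration)
        self._pools = {k: np.array(v, dtype=float) for k, v in by_window.items()}
        self._global = np.array([g.duration for g in gaps], dtype=float)
        self._first_delays = np.array(
            [s.first_read_delay for s in all_series.values()], dtype=float
        )

    def _pool_at(self, t: float) -> np.ndarray:
        k = int(t // self.window)
        for j in range(k, -1, -1):
            pool = self._pools.get(j)
            if pool is not None and len(pool):
                return pool
        return self._global

    def sample(self, stats) -> GapSpec:
        pool = self._pool_at(stats.t_now)
        dur = float(pool[int(self._rng.integers(len(pool)))])
        kind = "long" if dur >= self.long_gap_threshold else "short"
        return GapSpec(kind, dur)

    def initial_delay(self, stats) -> GapSpec:
        dur = float(
            self._first_delays[int(self._rng.integers(len(self._first_delays)))]
        )
        return GapSpec("short", dur)


class RollingWindowPerChannelSampler(GapSampler):
    """Samples the channel first, then gaps from a rolling time window.

    At construction each simulated channel is assigned a source channel
    drawn uniformly from the fitted run.  A draw at simulated time *t*
    resamples uniformly from that source channel's gaps whose start time
    lies within ``t ± window/2``, doubling the window symmetrically until
    it is non-empty.  The channel dies when *t* passes its source
    channel's last activity.
    """

    def __init__(
        self,
        all_series: Dict[int, ChannelGapSeries],
        n_channels: int,
        window: float = DEFAULT_ROLLING_WINDOW,
        seed: Optional[int] = None,
        long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
    ):
        if not all_series:
            raise ValueError("no source channels given")
        if window <= 0:
            raise ValueError("window must be > 0")
        self.window = float(window)
        self.long_gap_threshold = long_gap_threshold
        self._rng = np.random.default_rng(seed)
        ordered = [all_series[c] for c in sorted(all_series)]
        picks = self._rng.integers(len(ordered), size=n_channels)
        self._source: Dict[int, ChannelGapSeries] = {
            ch + 1: ordered[int(p)] for ch, p in enumerate(picks)
        }
        self._global_t = np.array(
            [g.t_at for s in ordered for g in s.gaps], dtype=float
        )
        self._global_d = np.array(
            [g.duration for s in ordered for g in s.gaps], dtype=float
        )

    @property
    def channel_assignment(self) -> Dict[int, int]:
        """Simulated channel -> assigned source channel number."""
        return {ch: s.channel for ch, s in self._source.items()}

    def _draw_from(self, t_at: np.ndarray, durations: np.ndarray, t: float) -> float:
        if not len(t_at):
            raise ValueError("source channel has no gaps")
        half = self.window / 2.0
        while True:
            mask = (t_at >= t - half) & (t_at <= t + half)
            n = int(mask.sum())
            if n:
                idx = int(self._rng.integers(n))
                return float(durations[mask][idx])
            half *= 2.0  # doubling terminates once [t-half, t+half] covers all gaps

    def sample(self, stats) -> GapSpec:
        src = self._source[stats.channel]
        if stats.t_now > src.channel_end_time:
            return GapSpec("inactive")
        if src.gaps:
            t_at = np.array([g.t_at for g in src.gaps], dtype=float)
            durs = src.durations
        elif len(self._global_d):
            t_at, durs = self._global_t, self._global_d
        else:
            return GapSpec("inactive")
        dur = self._draw_from(t_at, durs, stats.t_now)
        kind = "long" if dur >= self.long_gap_threshold else "short"
        return GapSpec(kind, dur)

    def initial_delay(self, stats) -> GapSpec:
        return GapSpec("short", self._source[stats.channel].first_read_delay)


def make_constant_gap_sampler(
    short_gap: float,
    long_gap: Optional[float] = None,
    long_gap_every_n_reads: Optional[int] = None,
) -> ConstantGapSampler:
    return ConstantGapSampler(short_gap, long_gap, long_gap_every_n_reads)


def make_replication_sampler(
    series_by_channel: Dict[int, ChannelGapSeries],
    n_channels: int,
    seed: Optional[int] = None,
    long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
) -> ReplicationGapSampler:
    return ReplicationGapSampler(series_by_channel, n_channels, seed, long_gap_threshold)


def make_windowed_aggregate_sampler(
    all_series: Dict[int, ChannelGapSeries],
    window: float,
    seed: Optional[int] = None,
    long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
) -> WindowedAggregateSampler:
    return WindowedAggregateSampler(all_series, window, seed, long_gap_threshold)


def make_rolling_window_per_channel_sampler(
    all_series: Dict[int, ChannelGapSeries],
    n_channels: int,
    window: float = DEFAULT_ROLLING_WINDOW,
    seed: Optional[int] = None,
    long_gap_threshold: float = DEFAULT_LONG_GAP_THRESHOLD,
) -> RollingWindowPerChannelSampler:
    return RollingWindowPerChannelSampler(
        all_series, n_channels, window, seed, long_gap_threshold
    )


_SCHEMA_VERSION = 1


def save_gap_series(
    series_by_channel: Dict[int, ChannelGapSeries], path: Union[str, Path]
) -> None:
    """Serialize fitted gap series to a versioned JSON file (``fit-gaps`` output)."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "channels": [
            {
                "channel": s.channel,
                "first_read_delay": s.first_read_delay,
                "channel_end_time": s.channel_end_time,
                "n_clamped": s.n_clamped,
                "gaps": [[g.t_at, g.duration] for g in s.gaps],
            }
            for s in series_by_channel.values()
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_gap_series(path: Union[str, Path]) -> Dict[int, ChannelGapSeries]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported fitted-params schema: {doc.get('schema_version')}")
    out: Dict[int, ChannelGapSeries] = {}
    for c in doc["channels"]:
        out[int(c["channel"])] = ChannelGapSeries(
            channel=int(c["channel"]),
            gaps=[Gap(t_at=t, duration=d) for t, d in c["gaps"]],
            first_read_delay=float(c["first_read_delay"]),
            channel_end_time=float(c["channel_end_time"]),
            n_clamped=int(c["n_clamped"]),
        )
    return out
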