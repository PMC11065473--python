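"""Per-channel sequencing state machine and the multi-channel engine.

Each channel holds exactly one element at any simulated time: a read in
progress, a short gap (pore loading), a long gap (temporary blockage), a
mux scan, or the absorbing permanently-inactive state.  Reads translocate
at a fixed speed (``bp_per_second``), preceded by a start delay that
models adapter passage.  After each read the channel's :class:`GapSampler`
decides what comes next; pool exhaustion or an ``inactive`` decision kills
the channel.

Time is a continuous float in simulated seconds.  Element boundaries fall
at exact times — a read of *L* bp occupies exactly
``start_delay_seconds + L / bp_per_second`` seconds — so the event log is
bit-reproducible for a given seed and action script, independent of how
the timeline is chopped into ticks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

from .gap_samplers import GapSampler, GapSpec, sample_gap
from .read_source import FullRead, ReadPool

__all__ = [
    "SimParams",
    "ReadEndReason",
    "FinishedRead",
    "ChannelStats",
    "Chunk",
    "ActionResult",
    "ReadInProgress",
    "ShortGap",
    "LongGap",
    "MuxScan",
    "Inactive",
    "Channel",
    "SequencerEngine",
]

_EPS = 1e-9


class ReadEndReason:
    """Why a read ended: completed naturally, rejected, cut by a mux scan,
    or flushed when the run stopped."""

    FINISHED = "finished"
    UNBLOCKED = "unblocked"
    MUX_SCAN_ENDED = "mux_scan_ended"
    RUN_ENDED = "run_ended"

    ALL = (FINISHED, UNBLOCKED, MUX_SCAN_ENDED, RUN_ENDED)


class ActionResult:
    SUCCEEDED = "succeeded"
    MISSED = "missed"


@dataclass
class SimParams:
    """Simulator configuration.

    ``bp_per_second`` defaults to 450, a typical ONT translocation speed.
    ``basecall_delay_per_bp`` delays *visibility* of each basepair to the
    client (it never affects the molecule's physical position).
    ``unblock_delay`` is appended after every rejection, and
    ``start_delay_seconds`` precedes each read (adapter time).
    """

    n_channels: int = 1
    bp_per_second: float = 450.0
    min_chunk_size: int = 200
    basecall_delay_per_bp: float = 0.0
    unblock_delay: float = 0.1
    start_delay_seconds: float = 1.0
    mux_scan_period: Optional[float] = None
    mux_scan_duration: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.bp_per_second <= 0:
            raise ValueError("bp_per_second must be > 0")
        for name in (
            "min_chunk_size",
            "basecall_delay_per_bp",
            "unblock_delay",
            "start_delay_seconds",
            "mux_scan_duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mux_scan_period is not None and self.mux_scan_period <= 0:
            raise ValueError("mux_scan_period must be > 0 or None")


@dataclass
class ChannelStats:
    """Running per-channel counters; all counters are monotone."""

    channel: int
    n_reads_finished: int = 0
    n_basepairs: int = 0
    n_rejections: int = 0
    n_missed_rejections: int = 0
    n_stop_receiving: int = 0
    t_now: float = 0.0
    channel_alive: bool = True

    def snapshot(self) -> "ChannelStats":
        return replace(self)


@dataclass(frozen=True)
class FinishedRead:
    """A sequenced (possibly truncated) read with timing and provenance."""

    sim_read_id: str
    original_read_id: str
    channel: int  # 1-based
    t_start: float
    duration: float
    sequence: str
    end_reason: str
    full_read_length: int = 0


@dataclass(frozen=True)
class Chunk:
    """New basecalled data from a read in progress, delivered at most once."""

    channel: int
    read_id: str
    offset: int  # 0-based basepair start within the read
    sequence: str
    t_sim: float


# ---- channel elements -------------------------------------------------------


@dataclass
class ReadInProgress:
    read: FullRead
    t_start: float
    stopped_receiving: bool = False
    bp_consumed_by_client: int = 0


@dataclass
class ShortGap:
    t_start: float
    duration: float
    # an unblock-delay element consults the sampler afterwards instead of
    # starting the next read directly
    then_sample_gap: bool = False


@dataclass
class LongGap:
    t_start: float
    duration: float


@dataclass
class MuxScan:
    t_start: float
    duration: float
    # remaining duration of a long gap interrupted by this scan, if any
    resume_long_gap_remaining: Optional[float] = None


@dataclass
class Inactive:
    pass


class Channel:
    """One channel's timeline.  Driven by :class:`SequencerEngine`."""

    def __init__(
        self,
        number: int,
        params: SimParams,
        pool: ReadPool,
        sampler: GapSampler,
    ):
        self.number = number
        self.params = params
        self.pool = pool
        self.sampler = sampler
        self.t = 0.0
        self.stats = ChannelStats(channel=number)
        self.element: object = None
        self._install_gap(self.sampler.initial_delay(self.stats))

    # -- element plumbing

    def _end_time(self, el) -> float:
        if isinstance(el, ReadInProgress):
            return (
                el.t_start
                + self.params.start_delay_seconds
                + el.read.length / self.params.bp_per_second
            )
        if isinstance(el, (ShortGap, LongGap, MuxScan)):
            return el.t_start + el.duration
        return math.inf

    def _install_gap(self, spec: GapSpec) -> None:
        if spec.kind == "inactive":
            self._die()
        elif spec.kind == "short":
            self.element = ShortGap(self.t, spec.duration)
        else:
            self.element = LongGap(self.t, spec.duration)

    def _die(self) -> None:
        self.element = Inactive()
        self.stats.channel_alive = False

    def _begin_gap(self) -> None:
        self.stats.t_now = self.t
        self._install_gap(sample_gap(self.sampler, self.stats))

    def _start_next_read(self) -> None:
        read = self.pool.next_read()
        if read is None:
            self._die()
        else:
            self.element = ReadInProgress(read=read, t_start=self.t)

    def _emit(self, el: ReadInProgress, sequence: str, reason: str) -> FinishedRead:
        fr = FinishedRead(
            sim_read_id=el.read.read_id,
            original_read_id=el.read.read_id,
            channel=self.number,
            t_start=el.t_start,
            duration=self.t - el.t_start,
            sequence=sequence,
            end_reason=reason,
            full_read_length=el.read.length,
        )
        self.stats.n_reads_finished += 1
        self.stats.n_basepairs += len(sequence)
        return fr

    def _physical_bp(self, el: ReadInProgress, t: float) -> int:
        """Basepairs physically sequenced by time ``t`` (molecule position)."""
        x = (t - el.t_start - self.params.start_delay_seconds) * self.params.bp_per_second
        return min(max(int(math.floor(x + _EPS)), 0), el.read.length)

    def _available_bp(self, el: ReadInProgress, t: float) -> int:
        """Basepairs basecalled and visible to the client by time ``t``.

        Basepair *k* becomes visible at
        ``t_start + start_delay + k/bp_per_second + basecall_delay_per_bp * k``.
        """
        per_bp = 1.0 / self.params.bp_per_second + self.params.basecall_delay_per_bp
        x = (t - el.t_start - self.params.start_delay_seconds) / per_bp
        return min(max(int(math.floor(x + _EPS)), 0), el.read.length)

    # -- public operations

    def advance(self, t_target: float) -> List[FinishedRead]:
        """Advance the timeline to ``t_target``, emitting completed reads.

        An element boundary falling exactly on ``t_target`` is processed
        (the interval is closed on the right).
        """
        if t_target < self.t - _EPS:
            raise ValueError(
                f"channel {self.number}: cannot advance backwards "
                f"({t_target} < {self.t})"
            )
        out: List[FinishedRead] = []
        while True:
            el = self.element
            if isinstance(el, Inactive):
                self.t = max(self.t, t_target)
                self.stats.t_now = self.t
                return out
            t_end = self._end_time(el)
            if t_end > t_target:
                self.t = t_target
                self.stats.t_now = self.t
                return out
            self.t = t_end
            self.stats.t_now = self.t
            if isinstance(el, ReadInProgress):
                out.append(self._emit(el, el.read.sequence, ReadEndReason.FINISHED))
                self._begin_gap()
            elif isinstance(el, ShortGap):
                if el.then_sample_gap:
                    self._begin_gap()
                else:
                    self._start_next_read()
            elif isinstance(el, LongGap):
                self._start_next_read()
            elif isinstance(el, MuxScan):
                rem = el.resume_long_gap_remaining
                if rem is not None and rem > 0:
                    self.element = LongGap(self.t, rem)
                else:
                    self._begin_gap()
            else:  # pragma: no cover
                raise AssertionError(f"unknown element {el!r}")

    def visible_chunk(self, t_now: Optional[float] = None) -> Optional[Chunk]:
        """Return accumulated new basecalled data, if at least
        ``min_chunk_size`` bp, marking it consumed; else ``None``."""
        if t_now is None:
            t_now = self.t
        el = self.element
        if not isinstance(el, ReadInProgress) or el.stopped_receiving:
            return None
        available = self._available_bp(el, t_now)
        new = available - el.bp_consumed_by_client
        if new < max(self.params.min_chunk_size, 1):
            return None
        chunk = Chunk(
            channel=self.number,
            read_id=el.read.read_id,
            offset=el.bp_consumed_by_client,
            sequence=el.read.sequence[el.bp_consumed_by_client : available],
            t_sim=t_now,
        )
        el.bp_consumed_by_client = available
        return chunk

    def unblock(
        self, read_id: Optional[str] = None
    ) -> tuple[str, Optional[FinishedRead]]:
        """Reject the read in progress (optionally only if its id matches).

        The emitted prefix is the molecule's physical position — basecall
        delay does not keep basepairs in the pore.  A fixed unblock delay
        is inserted before the next sampled gap.  Anything other than a
        matching read in progress is a missed action.
        """
        el = self.element
        if isinstance(el, ReadInProgress) and (
            read_id is None or read_id == el.read.read_id
        ):
            n = self._physical_bp(el, self.t)
            fr = self._emit(el, el.read.sequence[:n], ReadEndReason.UNBLOCKED)
            self.stats.n_rejections += 1
            self.element = ShortGap(
                self.t, self.params.unblock_delay, then_sample_gap=True
            )
            return ActionResult.SUCCEEDED, fr
        self.stats.n_missed_rejections += 1
        return ActionResult.MISSED, None

    def stop_receiving(self, read_id: Optional[str] = None) -> str:
        """Stop streaming the read's chunks; sequencing continues to the end."""
        el = self.element
        if isinstance(el, ReadInProgress) and (
            read_id is None or read_id == el.read.read_id
        ):
            if not el.stopped_receiving:
                el.stopped_receiving = True
                self.stats.n_stop_receiving += 1
            return ActionResult.SUCCEEDED
        return ActionResult.MISSED

    def interrupt_for_scan(self, duration: float) -> Optional[FinishedRead]:
        """Terminate the current element for a mux scan starting now.

        Reads emit their sequenced prefix; an interrupted long gap resumes
        afterwards with its remaining duration; short gaps are discarded;
        inactive channels are unaffected.
        """
        el = self.element
        if isinstance(el, Inactive):
            return None
        fr = None
        resume = None
        if isinstance(el, ReadInProgress):
            n = self._physical_bp(el, self.t)
            fr = self._emit(el, el.read.sequence[:n], ReadEndReason.MUX_SCAN_ENDED)
        elif isinstance(el, LongGap):
            resume = max(0.0, el.t_start + el.duration - self.t)
        self.element = MuxScan(self.t, duration, resume_long_gap_remaining=resume)
        return fr

    def flush_run_ended(self) -> Optional[FinishedRead]:
        """Emit the in-progress read's prefix at run stop and go inactive."""
        el = self.element
        fr = None
        if isinstance(el, ReadInProgress):
            n = self._physical_bp(el, self.t)
            fr = self._emit(el, el.read.sequence[:n], ReadEndReason.RUN_ENDED)
        self._die()
        return fr


class SequencerEngine:
    """All channels plus the shared pool, sampler, and mux-scan schedule.

    Channels are advanced together; automatic mux scans (if
    ``mux_scan_period`` is set) chop the advance at each scheduled scan
    start.  The complete event log of finished reads is kept in
    :attr:`finished_reads`.
    """

    def __init__(self, params: SimParams, pool: ReadPool, sampler: GapSampler):
        self.params = params
        self.pool = pool
        self.sampler = sampler
        self.channels = [
            Channel(i + 1, params, pool, sampler) for i in range(params.n_channels)
        ]
        self.t = 0.0
        self.finished_reads: List[FinishedRead] = []
        self._scan_until = -math.inf
        self._next_scan_idx = 1
        self._stopped = False

    def channel(self, number: int) -> Channel:
        if not 1 <= number <= len(self.channels):
            raise KeyError(f"unknown channel number {number}")
        return self.channels[number - 1]

    @property
    def scan_active(self) -> bool:
        return self.t < self._scan_until

    def advance(self, t_target: float) -> List[FinishedRead]:
        """Advance every channel to ``t_target``, triggering scheduled scans."""
        if t_target < self.t - _EPS:
            raise ValueError(f"cannot advance backwards ({t_target} < {self.t})")
        out: List[FinishedRead] = []
        period = self.params.mux_scan_period
        while True:
            t_next = t_target
            scan_now = False
            if period is not None:
                candidate = self._next_scan_idx * period
                while candidate <= self.t:  # skip scans already behind us
                    self._next_scan_idx += 1
                    candidate = self._next_scan_idx * period
                if candidate <= t_target:
                    t_next = candidate
                    scan_now = True
            for ch in self.channels:
                out.extend(ch.advance(t_next))
            self.t = t_next
            if scan_now:
                self._next_scan_idx += 1
                out.extend(
                    self.start_mux_scan(duration=self.params.mux_scan_duration)
                )
            if t_next >= t_target:
                break
        self.finished_reads.extend(out)
        return out

    def start_mux_scan(self, duration: Optional[float] = None) -> List[FinishedRead]:
        """Terminate every channel's current element and hold a scan window."""
        if self.scan_active:
            raise ValueError("a mux scan is already active")
        if duration is None:
            duration = self.params.mux_scan_duration
        out: List[FinishedRead] = []
        for ch in self.channels:
            fr = ch.interrupt_for_scan(duration)
            if fr is not None:
                out.append(fr)
        self._scan_until = self.t + duration
        return out

    def trigger_mux_scan(self, duration: Optional[float] = None) -> List[FinishedRead]:
        """Manually triggered scan; its reads also join the event log."""
        out = self.start_mux_scan(duration)
        self.finished_reads.extend(out)
        return out

    def unblock(self, channel: int, read_id: Optional[str] = None):
        result, fr = self.channel(channel).unblock(read_id)
        if fr is not None:
            self.finished_reads.append(fr)
        return result

    def stop_receiving(self, channel: int, read_id: Optional[str] = None) -> str:
        return self.channel(channel).stop_receiving(read_id)

    def visible_chunk(self, channel: int) -> Optional[Chunk]:
        return self.channel(channel).visible_chunk(self.t)

    def collect_stats(self) -> List[ChannelStats]:
        """Snapshot of every channel's counters; does not mutate state."""
        return [ch.stats.snapshot() for ch in self.channels]

    def finish_run(self) -> List[FinishedRead]:
        """Flush in-progress reads with end reason ``run_ended``; idempotent."""
        if self._stopped:
            return []
        self._stopped = True
        out = []
        for ch in self.channels:
            fr = ch.flush_run_ended()
            if fr is not None:
                out.append(fr)
        self.finished_reads.extend(out)
        return out
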