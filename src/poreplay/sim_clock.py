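"""Simulated-time / wall-time mapping and the engine drive loop.

Simulated time is decoupled from wall time by a dimensionless acceleration
factor: a run scheduled at acceleration *a* should reach simulated time
``(wall_now - t0) * a``.  The drive loop advances the engine in increments
of at most one tick, sleeping when ahead of schedule and warning (once)
when it falls behind by more than a lag tolerance.  Crucially, the chop
points of the simulated timeline — tick multiples, scripted action times,
stats intervals — depend only on simulated time, so the event log is
identical at any acceleration.
"""

from __future__ import annotations

import logging
import threading
import time
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

from .channel_engine import FinishedRead, SequencerEngine
from .output_writer import StatsReporter

logger = logging.getLogger(__name__)

__all__ = ["SimClock", "RunReport", "run"]

DEFAULT_TICK = 0.1  # simulated seconds


class SimClock:
    """Maps wall time to scheduled simulated time at a fixed acceleration."""

    def __init__(self, acceleration: float = 1.0):
        if acceleration <= 0:
            raise ValueError("acceleration must be > 0")
        self.acceleration = acceleration
        self.t0_wall: Optional[float] = None
        self.t_sim_now = 0.0
        self.max_lag = 0.0
        self.behind_flag = False

    def start(self) -> None:
        self.t0_wall = time.monotonic()

    @property
    def started(self) -> bool:
        return self.t0_wall is not None

    def now(self) -> float:
        """Current simulated engine time; monotone nondecreasing."""
        if not self.started:
            raise RuntimeError("clock not started")
        return self.t_sim_now

    def scheduled(self) -> float:
        """Simulated time the engine *should* have reached by now."""
        if not self.started:
            raise RuntimeError("clock not started")
        return (time.monotonic() - self.t0_wall) * self.acceleration

    def wall_for(self, t_sim: float) -> float:
        return self.t0_wall + t_sim / self.acceleration

    def record(self, t_sim: float) -> float:
        """Note engine progress; returns the current lag in simulated seconds."""
        self.t_sim_now = max(self.t_sim_now, t_sim)
        lag = max(0.0, self.scheduled() - self.t_sim_now)
        self.max_lag = max(self.max_lag, lag)
        return lag


@dataclass
class RunReport:
    """Outcome of one drive-loop run."""

    t_end: float
    wall_seconds: float
    max_lag: float
    lag_warning_fired: bool
    n_reads: int
    n_basepairs: int
    stopped_early: bool = False


def _boundaries(
    run_duration: float,
    tick: float,
    extra: Sequence[float],
) -> List[float]:
    """Chop points of the simulated timeline: tick multiples, the run end,
    and any extra (action / stats) times, sorted and deduplicated."""
    pts = set()
    t = tick
    while t < run_duration:
        pts.add(round(t / tick) * tick)
        t += tick
    pts.add(run_duration)
    for e in extra:
        if 0.0 < e <= run_duration:
            pts.add(e)
    return sorted(pts)


def run(
    engine: SequencerEngine,
    run_duration: float,
    acceleration: float = 1.0,
    tick: float = DEFAULT_TICK,
    clock: Optional[SimClock] = None,
    actions: Optional[Sequence[Tuple[float, Callable[[SequencerEngine], None]]]] = None,
    real_time: bool = True,
    lag_tolerance: Optional[float] = None,
    stats_interval: Optional[float] = None,
    stats_reporter: Optional[StatsReporter] = None,
    on_finished: Optional[Callable[[List[FinishedRead]], None]] = None,
    stop_event: Optional[threading.Event] = None,
) -> RunReport:
    """Drive the engine to ``run_duration`` simulated seconds.

    ``actions`` is a script of ``(t_sim, fn)`` pairs applied exactly when
    the engine reaches ``t_sim`` (the timeline is chopped there), making
    scripted sessions reproducible at any acceleration.  With
    ``real_time=False`` the loop never sleeps (offline replay).  On return
    the engine is stopped and in-progress reads are flushed with end
    reason ``run_ended``.
    """
    if tick <= 0:
        raise ValueError("tick must be > 0")
    if run_duration <= 0:
        raise ValueError("run_duration must be > 0")
    if clock is None:
        clock = SimClock(acceleration)
    if lag_tolerance is None:
        lag_tolerance = 2 * tick
    actions = sorted(actions or [], key=lambda a: a[0])
    action_times = [t for t, _ in actions]
    stats_times: List[float] = []
    if stats_interval:
        k = 1
        while k * stats_interval <= run_duration:
            stats_times.append(k * stats_interval)
            k += 1
    boundaries = _boundaries(run_duration, tick, list(action_times) + stats_times)

    clock.start()
    wall_start = time.monotonic()
    stopped_early = False
    ai = 0
    si = 0
    for t in boundaries:
        if stop_event is not None and stop_event.is_set():
            stopped_early = True
            break
        if real_time:
            dt = clock.wall_for(t) - time.monotonic()
            if dt > 0:
                time.sleep(dt)
        finished = engine.advance(t)
        if on_finished is not None and finished:
            on_finished(finished)
        while ai < len(actions) and actions[ai][0] <= t:
            actions[ai][1](engine)
            ai += 1
        while si < len(stats_times) and stats_times[si] <= t:
            if stats_reporter is not None:
                stats_reporter.report(engine.collect_stats(), stats_times[si])
            si += 1
        lag = clock.record(t)
        if lag > lag_tolerance and not clock.behind_flag:
            clock.behind_flag = True
            logger.warning(
                "simulator falling behind schedule: lag %.2f sim-s at t=%.2f "
                "(acceleration %.1f)",
                lag,
                t,
                clock.acceleration,
            )
    flushed = engine.finish_run()
    if on_finished is not None and flushed:
        on_finished(flushed)
    return RunReport(
        t_end=engine.t,
        wall_seconds=time.monotonic() - wall_start,
        max_lag=clock.max_lag,
        lag_warning_fired=clock.behind_flag,
        n_reads=len(engine.finished_reads),
        n_basepairs=sum(len(fr.sequence) for fr in engine.finished_reads),
        stopped_early=stopped_early,
    )
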