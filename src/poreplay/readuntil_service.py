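"""ReadUntil-style control API, in-process and over a wire protocol.

The in-process :class:`SimulatorService` mirrors the ONT ReadUntil
interaction style — batched polling for new basecalled chunks, batched
actions (``unblock``, ``stop_receiving``), and run control — on top of a
:class:`~poreplay.channel_engine.SequencerEngine`.  Chunks carry
basecalled sequence and simulated timestamps, never wall timestamps, so
client behavior is invariant under acceleration.

The wire layer speaks newline-delimited JSON over TCP (see
``docs/wire_protocol.md`` for the versioned message schema:
GetChunksRequest/Response, ActionRequest/Response,
ControlRequest/Response).  :class:`WireClient` exposes exactly the same
methods and return types as the in-process service, so a client session
is field-for-field identical over either path.
"""

from __future__ import annotations

import json
import logging
import socket
import socketserver
import threading
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Union

from .channel_engine import (
    ChannelStats,
    Chunk,
    SequencerEngine,
)
from .sim_clock import DEFAULT_TICK, SimClock

logger = logging.getLogger(__name__)

__all__ = [
    "ActionRequest",
    "ActionResponse",
    "SimulatorService",
    "WireServer",
    "WireClient",
    "PROTOCOL_VERSION",
]

PROTOCOL_VERSION = 1

ACTION_KINDS = ("unblock", "stop_receiving")


@dataclass(frozen=True)
class ActionRequest:
    channel: int
    action: str  # "unblock" | "stop_receiving"
    read_id: Optional[str] = None


@dataclass(frozen=True)
class ActionResponse:
    channel: int
    action: str
    read_id: Optional[str]
    result: str  # "succeeded" | "missed" | "error"
    message: str = ""


class SimulatorService:
    """Thread-safe facade over one engine.

    ``start()`` launches the accelerated drive loop in a background
    thread; API calls are applied under a lock at the engine's current
    simulated time (i.e. at the most recent tick boundary), so an idle
    client never stalls simulated time and action latency is at most one
    tick.  Without ``start()`` the service can be stepped manually with
    :meth:`advance_to` — useful for deterministic scripted sessions.
    """

    def __init__(
        self,
        engine: SequencerEngine,
        acceleration: float = 1.0,
        tick: float = DEFAULT_TICK,
    ):
        self.engine = engine
        self.acceleration = acceleration
        self.tick = tick
        self._lock = threading.RLock()
        self._thread: Optional[threading.Thread] = None
        self._stop_event = threading.Event()
        self._running = False
        self.clock: Optional[SimClock] = None
        self.report = None

    # -- run control

    @property
    def running(self) -> bool:
        return self._running

    def start(self, run_duration: float) -> None:
        """Launch the clock loop; error if already running."""
        with self._lock:
            if self._running:
                raise RuntimeError("simulation already running")
            self._running = True
            self._stop_event = threading.Event()
            self.clock = SimClock(self.acceleration)

        def _loop():
            try:
                self.report = _locked_run(
                    self, run_duration, self.clock, self._stop_event
                )
            finally:
                self._running = False

        self._thread = threading.Thread(target=_loop, daemon=True)
        self._thread.start()

    def stop(self) -> None:
        """Stop the loop and flush in-progress reads; idempotent."""
        self._stop_event.set()
        if self._thread is not None:
            self._thread.join()
            self._thread = None
        with self._lock:
            self.engine.finish_run()
            self._running = False

    def advance_to(self, t_sim: float) -> None:
        """Manually advance simulated time (only when the loop is not running)."""
        if self._running:
            raise RuntimeError("cannot step manually while the loop is running")
        with self._lock:
            self.engine.advance(t_sim)

    # -- ReadUntil API

    def get_basecalled_read_chunks(
        self, channels: Optional[Sequence[int]] = None
    ) -> List[Chunk]:
        """New basecalled data per requested channel (all by default).

        At most one chunk per channel per call; consumed basepairs are
        never re-delivered.  Unknown channel numbers raise ``KeyError``.
        """
        with self._lock:
            if channels is None:
                channels = range(1, len(self.engine.channels) + 1)
            else:
                for c in channels:
                    self.engine.channel(c)  # raises KeyError naming it
            chunks = []
            for c in channels:
                chunk = self.engine.visible_chunk(c)
                if chunk is not None:
                    chunks.append(chunk)
            return chunks

    def perform_actions(
        self, requests: Sequence[Union[ActionRequest, dict]]
    ) -> List[ActionResponse]:
        """Apply actions in order; one response each, order preserved.

        A malformed entry (unknown action kind, unknown channel) yields an
        ``error`` response for that entry only.
        """
        out: List[ActionResponse] = []
        with self._lock:
            for req in requests:
                if isinstance(req, dict):
                    req = ActionRequest(
                        channel=req["channel"],
                        action=req["action"],
                        read_id=req.get("read_id"),
                    )
                if req.action not in ACTION_KINDS:
                    out.append(
                        ActionResponse(
                            req.channel,
                            req.action,
                            req.read_id,
                            "error",
                            f"unknown action kind {req.action!r}",
                        )
                    )
                    continue
                try:
                    if req.action == "unblock":
                        result = self.engine.unblock(req.channel, req.read_id)
                    else:
                        result = self.engine.stop_receiving(req.channel, req.read_id)
                    out.append(
                        ActionResponse(req.channel, req.action, req.read_id, result)
                    )
                except KeyError as e:
                    out.append(
                        ActionResponse(
                            req.channel, req.action, req.read_id, "error", str(e)
                        )
                    )
        return out

    # -- control commands

    def trigger_mux_scan(self, duration: Optional[float] = None) -> int:
        """Start a mux scan now; returns the number of reads it terminated."""
        with self._lock:
            return len(self.engine.trigger_mux_scan(duration))

    def get_stats(self) -> List[ChannelStats]:
        with self._lock:
            return self.engine.collect_stats()

    def get_run_info(self) -> dict:
        with self._lock:
            p = self.engine.params
            return {
                "protocol_version": PROTOCOL_VERSION,
                "n_channels": p.n_channels,
                "bp_per_second": p.bp_per_second,
                "min_chunk_size": p.min_chunk_size,
                "basecall_delay_per_bp": p.basecall_delay_per_bp,
                "unblock_delay": p.unblock_delay,
                "start_delay_seconds": p.start_delay_seconds,
                "mux_scan_period": p.mux_scan_period,
                "mux_scan_duration": p.mux_scan_duration,
                "seed": p.seed,
                "acceleration": self.acceleration,
                "tick": self.tick,
                "t_sim": self.engine.t,
                "running": self._running,
                "n_reads_finished": len(self.engine.finished_reads),
                "reads_remaining": self.engine.pool.n_remaining,
            }


def _locked_run(service, run_duration, clock, stop_event):
    """Drive loop that takes the service lock around each engine advance."""
    import time as _time

    engine = service.engine
    tick = service.tick
    t = 0.0
    clock.start()
    wall_start = _time.monotonic()
    lag_tolerance = 2 * tick
    stopped_early = False
    while t < run_duration:
        t = min(t + tick, run_duration)
        dt = clock.wall_for(t) - _time.monotonic()
        if dt > 0:
            _time.sleep(dt)
        if stop_event.is_set():
            stopped_early = True
            break
        with service._lock:
            engine.advance(t)
        lag = clock.record(t)
        if lag > lag_tolerance and not clock.behind_flag:
            clock.behind_flag = True
            logger.warning("simulator falling behind: lag %.2f sim-s", lag)
    with service._lock:
        engine.finish_run()
    from .sim_clock import RunReport

    return RunReport(
        t_end=engine.t,
        wall_seconds=_time.monotonic() - wall_start,
        max_lag=clock.max_lag,
        lag_warning_fired=clock.behind_flag,
        n_reads=len(engine.finished_reads),
        n_basepairs=sum(len(fr.sequence) for fr in engine.finished_reads),
        stopped_early=stopped_early,
    )


# ---- wire protocol ----------------------------------------------------------


def _stats_to_dict(s: ChannelStats) -> dict:
    return asdict(s)


def _dict_to_stats(d: dict) -> ChannelStats:
    return ChannelStats(**d)


def _chunk_to_dict(c: Chunk) -> dict:
    return asdict(c)


def _dict_to_chunk(d: dict) -> Chunk:
    return Chunk(**d)


class _Handler(socketserver.StreamRequestHandler):
    def handle(self):
        service: SimulatorService = self.server.service  # type: ignore[attr-defined]
        for line in self.rfile:
            line = line.strip()
            if not line:
                continue
            try:
                req = json.loads(line)
                resp = self._dispatch(service, req)
            except Exception as e:  # malformed request or service error
                resp = {"type": "ErrorResponse", "error": str(e)}
            self.wfile.write((json.dumps(resp) + "\n").encode())
            self.wfile.flush()

    @staticmethod
    def _dispatch(service: SimulatorService, req: dict) -> dict:
        kind = req.get("type")
        if kind == "GetChunksRequest":
            chunks = service.get_basecalled_read_chunks(req.get("channels"))
            return {
                "type": "GetChunksResponse",
                "chunks": [_chunk_to_dict(c) for c in chunks],
            }
        if kind == "ActionRequest":
            responses = service.perform_actions(req.get("actions", []))
            return {
                "type": "ActionResponse",
                "responses": [asdict(r) for r in responses],
            }
        if kind == "ControlRequest":
            command = req.get("command")
            args = req.get("args", {})
            if command == "start":
                service.start(run_duration=float(args["run_duration"]))
                result = {"started": True}
            elif command == "stop":
                service.stop()
                result = {"stopped": True}
            elif command == "trigger_mux_scan":
                n = service.trigger_mux_scan(args.get("duration"))
                result = {"n_reads_terminated": n}
            elif command == "get_stats":
                result = {"stats": [_stats_to_dict(s) for s in service.get_stats()]}
            elif command == "get_run_info":
                result = {"run_info": service.get_run_info()}
            else:
                raise ValueError(f"unknown control command {command!r}")
            return {"type": "ControlResponse", "command": command, "result": result}
        raise ValueError(f"unknown request type {kind!r}")


class WireServer:
    """Serves a :class:`SimulatorService` over newline-delimited JSON/TCP."""

    def __init__(self, service: SimulatorService, host: str = "127.0.0.1", port: int = 0):
        self._server = socketserver.ThreadingTCPServer(
            (host, port), _Handler, bind_and_activate=True
        )
        self._server.daemon_threads = True
        self._server.service = service  # type: ignore[attr-defined]
        self._thread: Optional[threading.Thread] = None

    @property
    def address(self) -> tuple:
        return self._server.server_address

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    def start(self) -> None:
        self._thread = threading.Thread(
            target=self._server.serve_forever, daemon=True
        )
        self._thread.start()

    def serve_forever(self) -> None:
        self._server.serve_forever()

    def shutdown(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self._thread is not None:
            self._thread.join()
            self._thread = None


class WireClient:
    """Client for :class:`WireServer` mirroring the in-process service API."""

    def __init__(self, host: str = "127.0.0.1", port: int = 0, timeout: float = 30.0):
        self._sock = socket.create_connection((host, port), timeout=timeout)
        self._rfile = self._sock.makefile("r")

    def close(self) -> None:
        self._rfile.close()
        self._sock.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _call(self, req: dict) -> dict:
        self._sock.sendall((json.dumps(req) + "\n").encode())
        line = self._rfile.readline()
        if not line:
            raise ConnectionError("server closed the connection")
        resp = json.loads(line)
        if resp.get("type") == "ErrorResponse":
            raise RuntimeError(resp["error"])
        return resp

    def get_basecalled_read_chunks(
        self, channels: Optional[Sequence[int]] = None
    ) -> List[Chunk]:
        resp = self._call(
            {
                "type": "GetChunksRequest",
                "channels": list(channels) if channels is not None else None,
            }
        )
        return [_dict_to_chunk(c) for c in resp["chunks"]]

    def perform_actions(
        self, requests: Sequence[Union[ActionRequest, dict]]
    ) -> List[ActionResponse]:
        actions = []
        for r in requests:
            if isinstance(r, ActionRequest):
                actions.append(
                    {"channel": r.channel, "action": r.action, "read_id": r.read_id}
                )
            else:
                actions.append(dict(r))
        resp = self._call({"type": "ActionRequest", "actions": actions})
        return [ActionResponse(**r) for r in resp["responses"]]

    def _control(self, command: str, **args) -> dict:
        resp = self._call(
            {"type": "ControlRequest", "command": command, "args": args}
        )
        return resp["result"]

    def start(self, run_duration: float) -> None:
        self._control("start", run_duration=run_duration)

    def stop(self) -> None:
        self._control("stop")

    def trigger_mux_scan(self, duration: Optional[float] = None) -> int:
        args = {} if duration is None else {"duration": duration}
        return self._control("trigger_mux_scan", **args)["n_reads_terminated"]

    def get_stats(self) -> List[ChannelStats]:
        return [_dict_to_stats(s) for s in self._control("get_stats")["stats"]]

    def get_run_info(self) -> dict:
        return self._control("get_run_info")["run_info"]
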