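# Wire protocol (version 1)

The simulator is exposed over TCP using newline-delimited JSON: each
request is one JSON object terminated by `\n`, answered by exactly one
JSON object terminated by `\n`, over a persistent connection.  The
channel is insecure by design — this is a local benchmarking tool.

All timestamps are **simulated seconds**; wall time never appears on the
wire, so client behavior is invariant under acceleration.  Sequences
travel as plain uppercase text.

## Messages

### GetChunksRequest / GetChunksResponse

```json
{"type": "GetChunksRequest", "channels": [1, 2, 3]}
{"type": "GetChunksResponse", "chunks": [
  {"channel": 1, "read_id": "...", "offset": 0, "sequence": "ACGT...", "t_sim": 12.3}
]}
```

`channels: null` polls every channel.  At most one chunk per channel per
call — the accumulated new basepairs since the last poll, only if at
least `min_chunk_size` are available.  Delivered basepairs are never
re-delivered.  A read under `stop_receiving` returns no further chunks.

### ActionRequest / ActionResponse

```json
{"type": "ActionRequest", "actions": [
  {"channel": 2, "action": "unblock", "read_id": "..."},
  {"channel": 5, "action": "stop_receiving", "read_id": null}
]}
{"type": "ActionResponse", "responses": [
  {"channel": 2, "action": "unblock", "read_id": "...", "result": "succeeded", "message": ""},
  {"channel": 5, "action": "stop_receiving", "read_id": null, "result": "missed", "message": ""}
]}
```

Actions are applied in order; each entry yields one response preserving
request identity.  `read_id: null` targets whatever read is in progress.
If the target read is no longer present, `result` is `"missed"`.  A
malformed entry (unknown action kind or channel) yields `"error"` for
that entry only.

### ControlRequest / ControlResponse

```json
{"type": "ControlRequest", "command": "start", "args": {"run_duration": 3600}}
{"type": "ControlResponse", "command": "start", "result": {"started": true}}
```

Commands: `start` (errors if already running), `stop` (idempotent),
`trigger_mux_scan` (optional `duration` arg; errors if a scan is
active), `get_stats` (per-channel counter snapshots), `get_run_info`
(simulator parameters, current simulated time, progress).

### Errors

Any failed request is answered with

```json
{"type": "ErrorResponse", "error": "human-readable message"}
```

and the connection stays open.
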