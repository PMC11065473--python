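# Methods

## The model

`poreplay` simulates an Oxford Nanopore sequencer at the level that
matters for selective-sequencing algorithms: reads, time, and the
ReadUntil control surface.  It does not model pore physics or
basecalling errors — input reads are played back verbatim, and the
client receives basecalled sequence rather than raw signal, which
removes the GPU/basecaller from the benchmarking loop.

A flowcell is `n_channels` independent channels drawing full reads from
one shared, seeded-shuffled pool, **on demand**: a channel requests its
next read only when its previous element ends, so channels that die
early never consume pool reads.  At any simulated time a channel holds
exactly one element:

- **read in progress** — the molecule translocates at `bp_per_second`
  (default 450 bp/s, a typical ONT translocation speed), preceded by
  `start_delay_seconds` of adapter passage during which no basepairs are
  visible.  A read of `L` bp occupies exactly
  `start_delay_seconds + L / bp_per_second` seconds; there is no drift.
- **short gap** — pore-loading time between reads.
- **long gap** — a temporarily blocked channel.
- **mux scan** — a flowcell-wide interruption window.
- **inactive** — permanent channel death; absorbing.

After each read the channel's *gap sampler* decides what follows: a
short gap, a long gap, or death.  Pool exhaustion also kills the
channel.

### Chunk visibility vs. physical position

Two clocks govern a read.  The *physical* position (what has actually
left the pore) is `floor((t - t_start - start_delay) * bp_per_second)`.
The *client-visible* position additionally pays a basecalling latency of
`basecall_delay_per_bp` seconds per basepair: basepair `k` becomes
visible at `t_start + start_delay + k/bp_per_second +
k * basecall_delay_per_bp`.  Chunk polling returns the accumulated new
visible basepairs once at least `min_chunk_size` (default 200 bp) have
accrued, and never re-delivers a basepair.  **Rejection truncates at the
physical position**: the molecule leaves the pore at rejection time; the
client merely saw its data late.  `basecall_delay_per_bp` defaults to 0
(an idealized instant basecaller); set it to model a loaded basecaller.

### Actions

`unblock` terminates a matching read in progress, emits its physical
prefix, and inserts a fixed `unblock_delay` (default 0.1 s, the order of
a real voltage-reversal flick) before the next sampled gap.
`stop_receiving` silences a read's chunks while sequencing continues;
the full read is still emitted at its natural end.  Either action on a
read that is no longer present is counted as **missed** and reported
through the return value, exactly as a real ReadUntil client would
observe.  Actions may carry a read id (a mismatch is missed) or none
(apply to whatever read is in progress).

### Mux scans

A scan terminates every channel's current element at the scan start:
reads are emitted with their physical prefix (end reason
`mux_scan_ended`), short gaps are discarded, and an interrupted long gap
resumes after the scan with exactly its remaining duration.  Scans
auto-trigger every `mux_scan_period` (off by default; duration default
120 s) and can be triggered manually; overlapping scans are an error.

### Time and acceleration

Simulated time is a continuous float in seconds; element boundaries are
processed closed-on-the-right.  The drive loop chops the timeline into
ticks (default 0.1 s) plus scripted action times and stats intervals —
all simulated quantities — and sleeps in wall time when ahead of
schedule at acceleration `a` (scheduled sim time is
`(wall_now - t0) * a`).  Because the chop points are independent of
wall time, the event log is identical at any acceleration; this is the
core correctness property of the clock, and is what the acceptance
suite checks byte-for-byte on sequencing summaries.  If the engine
falls behind schedule by more than `lag_tolerance` (default 2 ticks) a
warning is issued once; results remain correct, only wall-clock realism
suffers.  Actions arriving through the live service are applied at the
engine's current tick, so live action latency is at most one tick.

### Randomness

Two independent RNG streams derive from the configuration: the pool
shuffle and the gap sampling (each sampler owns a
`numpy.random.Generator`).  Identical seeds and call sequences give
identical runs.

## Gap samplers

Fitted from an ONT sequencing-summary TSV (required columns `read_id`,
`channel`, `start_time`, `duration`, `sequence_length_template`).  Per
channel, records are sorted by start time and the gap after read *i* is
`start_{i+1} - (start_i + duration_i)`; negative gaps (overlapping
records, a real basecaller artifact) are clamped to zero with a counted
warning.  Mux-scan windows present in the source run are not excised;
gaps are taken verbatim.  Gaps at or above `long_gap_threshold`
(default 10 s, configurable — the boundary case counts as long) are
classified long.

- **constant** — fixed short gaps, optionally a fixed long gap every
  *n* reads; never dies.  `short_gap=0` gives back-to-back reads, the
  peak-throughput stress case.  Useful for prototyping, not realism.
- **replication** — replays a source channel's gap sequence in order;
  dies on exhaustion or past the source channel's last activity.
  Closest to the source run, at the cost of memorizable structure.
- **windowed aggregate** — pools all channels' gaps into fixed time
  windows by gap start time and resamples uniformly within the current
  window (falling back to the nearest earlier non-empty window, then
  the global pool).  Resamples only; never interpolates.
- **rolling window per channel** (recommended) — assigns each simulated
  channel a uniformly drawn source channel, then resamples that
  channel's gaps from a window of `window` seconds (default 600 s)
  centered on the current simulated time, doubling the window until
  non-empty; dies past the source channel's end time.  Reproduces
  per-channel throughput structure while varying the fine timing.
  Default window: wide enough to be robust on sparse channels, narrow
  enough to track run-scale throughput decay.  A source channel with no
  gaps at all falls back to the global gap pool.

Channel-count mismatches reuse source channels by index and fill the
surplus by seeded uniform draws with replacement.  The delay before a
channel's *first* read is not sampled: fitted samplers replay the source
channel's observed first-read delay; the constant sampler uses one
short gap.  The per-read start delay is a constant (the paper-level
abstraction of adapter time); a per-read distribution can be added by
subclassing the sampler hook.

## Output

Finished reads are appended to FASTA in batches (a crash loses at most
one batch) with a metadata header

```
>{record_id} full_read_id=... ch=... start_time=... duration=... end_reason=... seq_len=...
```

from which a sequencing summary is rebuilt in O(records) without
basecalling.  Floats are serialized with `repr` so the header round-trip
is lossless.  End reasons map to ONT-like vocabulary
(`signal_positive`, `data_service_unblock_mux_change`, `mux_change`,
`signal_negative`); the internal enum is authoritative.  Truncated reads
with NanoSim-style ids get the id's reference-length field rewritten:
the head portion of the read is consumed first, then the middle, then
the tail, and the middle (reference-length) field is rescaled by the
consumed middle fraction — the simplest convention consistent with
NanoSim's head/middle/tail semantics; the `full_read_id` key always
keeps the original id.  Zero-length truncations (rejections during the
start delay) cannot be FASTA records; they are counted separately and
appear only in summaries built from the event log.

The raw-signal prototype maps each k-mer window to a current level from
a pore-model table plus Gaussian noise, `samples_per_base` samples per
window; windows containing `N` map to the mean table level.  A
deterministic synthetic 6-mer table in a plausible current range
(60–130 pA) ships in code so the path is testable offline; ONT k-mer
model TSVs (`kmer`, `level_mean`) are accepted when provided.

## Synthetic fixtures

The generator emulates the gap structure the simulator models — a
first-read delay, alternating reads and gaps, occasional blockages,
uniform channel death times — with lognormal read lengths (default
median 5 kb, σ=0.5 log-bp) and exponential gaps (short mean 1 s, long
mean 60 s at probability 0.05 per gap), chosen as realistic for a small
MinION-class run.  It returns the exact gap series it used, so fitting
is checked against ground truth.  It deliberately does **not** model
basecalling errors, quality, speed variation, or rejection-induced pore
deterioration; tests passing on these fixtures show the simulator's
bookkeeping and fitting are correct, not that any particular real
flowcell is reproduced.

## Problem sizes and numerical choices

The test and acceptance workloads are desk-scale by design: a
64-channel run over a 2,000-read pool with scripted random actions,
exhaustive small-grid comparisons against an independent discrete-event
replay (≤2 channels, ≤20 reads), 10,000-draw two-sample KS checks at
α=0.01 for the resampling samplers, and 10,000-record summary round
trips.  The KS checks draw at operationally advancing times (each draw
time incremented by a read duration plus the drawn gap, as in an
actual run): window-local resampling evaluated at *uniformly random*
times over-weights gaps from sparse, long-gap regions of the timeline,
which is a property of the estimator's evaluation, not of its use.  Basepair counts use `floor` with a 1e-9 guard against float
dust at exact element boundaries.  Gap durations of zero are legal and
produce back-to-back elements processed in the same advance.  The
engine processes channels in channel order within each tick, which
fixes the pool-dispensing order and makes shared-RNG sampler draws
reproducible.

## Known limitations

No raw-signal output formats (FAST5/POD5), no quality scores or FASTQ,
no per-pore voltage or deterioration modeling, no MinKNOW protocol
compatibility (the wire schema is this package's own, documented in
`wire_protocol.md`).  Real-time fidelity at extreme accelerations is
bounded by the host: the event log stays exact, but wall-clock pacing
degrades with a logged warning.
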