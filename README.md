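# poreplay

A lightweight simulator of an Oxford Nanopore sequencer with a
ReadUntil-style control API, for developing and benchmarking **selective
sequencing** (adaptive sampling) decision algorithms without a flowcell,
basecaller, or GPU.

Selective sequencing uses ONT's ReadUntil interface to act on reads
while they are still in the pore: *unblock* (reject) a molecule by
reversing the pore voltage, or *stop receiving* its data while
sequencing continues.  The quality of the decision algorithm (which
read to reject, and how early) determines the enrichment achieved, and
tuning it on real flowcells is slow and expensive.  `poreplay` replays a
pool of full reads (e.g. from NanoSim, or from a real run) across many
simulated channels in real or accelerated time, with the phenomena that
matter for decision timing:

- per-read start delays (adapter passage), translocation at a
  configurable speed (default 450 bp/s), and a basecalling latency model;
- short gaps (pore loading), long gaps (temporary blockages), permanent
  channel death, and flowcell-wide mux scans — with gap behavior fitted
  from a real run's sequencing summary via four strategies (constant,
  replication, windowed aggregate, and the recommended
  rolling-window-per-channel);
- chunked **basecalled** data streaming with a minimum chunk size,
  `unblock` with a post-rejection delay and *missed-action* reporting,
  and `stop_receiving` semantics;
- FASTA output whose metadata headers reconstruct an ONT-style
  sequencing summary with no basecalling, NanoSim read-id rewriting for
  truncated reads, per-channel statistics, and a prototype k-mer
  pore-model conversion to raw signal.

The control API is available in-process and over a small JSON/TCP wire
protocol (`docs/wire_protocol.md`), so decision algorithms in any
language can drive the simulator.  The event log is bit-identical at
any acceleration factor — wall time only affects pacing, never results.

See `docs/methods.md` for the model, its assumptions, and all defaults.

## Worked example

Generate synthetic inputs, fit gap behavior from a (here: synthetic)
sequencing summary, and run an accelerated 8-channel simulation:

```bash
poreplay make-fixtures reads --out reads.fasta --n 400 --seed 7
poreplay make-fixtures summary --out source_summary.tsv --seed 7

cat > config.yaml <<EOF
n_channels: 8
min_chunk_size: 200
start_delay_seconds: 1.0
unblock_delay: 0.1
seed: 1
EOF

poreplay simulate --reads reads.fasta --config config.yaml \
    --run-duration 120 --acceleration 60 --out-dir run8 \
    --gap-strategy rolling_window_per_channel --summary source_summary.tsv
```

which prints

```
simulated 120.0 s in 2.0 wall-s: 62 reads, 296375 bp, max lag 0.12 s
```

— 120 simulated seconds ran in 2 wall seconds (acceleration 60); the 8
channels completed 62 reads totalling 296,375 bp, and the engine stayed
within 0.12 simulated seconds of schedule (a warning is logged if it
falls behind by more than the lag tolerance).  `run8/` now contains
`reads.fasta` (records carry metadata headers, e.g.
`>... full_read_id=... ch=1 start_time=0.58456130735793 duration=6.151111111111111
end_reason=signal_positive seq_len=2318`), the reconstructed
`sequencing_summary.txt` (one row per read), and `channel_stats.tsv`
(per-channel counters over time).  The summary of one simulated run can
itself be fitted for the next:

```bash
poreplay fit-gaps --summary run8/sequencing_summary.txt --out fitted.json
poreplay make-summary --fasta run8/reads.fasta --out rebuilt_summary.tsv
```

To drive the simulator interactively (e.g. from a decision algorithm),
`poreplay serve --reads reads.fasta --config config.yaml --port 8472`
exposes chunk polling, actions, and run control over the wire protocol;
in Python, `poreplay.SimulatorService` offers the same API in-process.

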