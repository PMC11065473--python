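"""Persisting simulator output.

Finished reads go to FASTA with a metadata header that carries everything
needed to rebuild an ONT-style sequencing summary without basecalling:

    >{record_id} full_read_id=... ch=... start_time=... duration=... end_reason=... seq_len=...

Truncated reads with a NanoSim-style id get the id's reference-length
field rewritten to reflect the truncation; the ``full_read_id`` header key
always keeps the original id.  End reasons are written with ONT-like
vocabulary (``signal_positive``, ``data_service_unblock_mux_change``,
``mux_change``, ``signal_negative``).

A prototype conversion of basecalled sequence to synthetic raw current is
provided via a k-mer pore model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .channel_engine import ChannelStats, FinishedRead, ReadEndReason
from .read_source import parse_nanosim_id, rewrite_nanosim_id

logger = logging.getLogger(__name__)

__all__ = [
    "END_REASON_TOKENS",
    "TOKEN_END_REASONS",
    "record_id_for",
    "format_fasta_header",
    "parse_fasta_header",
    "write_finished_reads",
    "OutputWriter",
    "summary_from_finished_reads",
    "build_sequencing_summary",
    "StatsReporter",
    "PoreModel",
    "default_pore_model",
    "load_pore_model",
    "sequence_to_raw_signal",
]

#: Internal end-reason enum -> ONT-like summary token.
END_REASON_TOKENS = {
    ReadEndReason.FINISHED: "signal_positive",
    ReadEndReason.UNBLOCKED: "data_service_unblock_mux_change",
    ReadEndReason.MUX_SCAN_ENDED: "mux_change",
    ReadEndReason.RUN_ENDED: "signal_negative",
}
TOKEN_END_REASONS = {v: k for k, v in END_REASON_TOKENS.items()}

_HEADER_KEYS = (
    "full_read_id",
    "ch",
    "start_time",
    "duration",
    "end_reason",
    "seq_len",
)

SUMMARY_COLUMNS = [
    "read_id",
    "channel",
    "start_time",
    "duration",
    "sequence_length_template",
    "end_reason",
    "passes_filtering",
]


def record_id_for(fr: FinishedRead) -> str:
    """FASTA record id: the NanoSim id rewritten for truncation, else the
    original read id."""
    if fr.end_reason != ReadEndReason.FINISHED:
        meta = parse_nanosim_id(fr.original_read_id)
        if meta is not None and fr.full_read_length:
            return rewrite_nanosim_id(meta, len(fr.sequence), fr.full_read_length)
    return fr.original_read_id


def format_fasta_header(fr: FinishedRead, record_id: Optional[str] = None) -> str:
    """Header line (without ``>``): record id plus space-separated key=value
    metadata; values never contain spaces, floats use ``repr`` so the
    header round-trips losslessly."""
    if record_id is None:
        record_id = record_id_for(fr)
    return (
        f"{record_id} full_read_id={fr.original_read_id} ch={fr.channel}"
        f" start_time={fr.t_start!r} duration={fr.duration!r}"
        f" end_reason={END_REASON_TOKENS[fr.end_reason]} seq_len={len(fr.sequence)}"
    )


def parse_fasta_header(description: str) -> dict:
    """Inverse of :func:`format_fasta_header`; raises ``ValueError`` naming
    the record and the missing key if the header is incomplete."""
    parts = description.split()
    record_id = parts[0]
    kv = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            kv[k] = v
    for key in _HEADER_KEYS:
        if key not in kv:
            raise ValueError(f"record {record_id!r}: header missing key {key!r}")
    return {
        "read_id": record_id,
        "full_read_id": kv["full_read_id"],
        "channel": int(kv["ch"]),
        "start_time": float(kv["start_time"]),
        "duration": float(kv["duration"]),
        "end_reason": kv["end_reason"],
        "seq_len": int(kv["seq_len"]),
    }


def write_finished_reads(
    batch: Sequence[FinishedRead],
    out_dir: Union[str, Path],
    fasta_name: str = "reads.fasta",
) -> Path:
    """Append a batch of finished reads to ``out_dir/fasta_name``.

    Zero-length reads (rejected during the start delay) cannot be FASTA
    records and are skipped here; they still appear in summaries built
    from the event log.  Returns the FASTA path.
    """
    if not batch:
        raise ValueError("empty batch")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / fasta_name
    with open(path, "a") as fh:
        for fr in batch:
            if not fr.sequence:
                continue
            fh.write(f">{format_fasta_header(fr)}\n{fr.sequence}\n")
        fh.flush()
    return path


class OutputWriter:
    """Streams finished reads to FASTA in batches and keeps the event log.

    Batches are flushed whenever ``batch_size`` reads accumulate (and on
    :meth:`close`), so a crash loses at most one batch.  Zero-length reads
    are counted separately and appear only in the summary.
    """

    def __init__(
        self,
        out_dir: Union[str, Path],
        batch_size: int = 100,
        fasta_name: str = "reads.fasta",
    ):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.batch_size = batch_size
        self.fasta_name = fasta_name
        self.records: List[FinishedRead] = []
        self.n_zero_length = 0
        self._pending: List[FinishedRead] = []
        self._closed = False

    @property
    def fasta_path(self) -> Path:
        return self.out_dir / self.fasta_name

    def add(self, finished: Iterable[FinishedRead]) -> None:
        for fr in finished:
            self.records.append(fr)
            if fr.sequence:
                self._pending.append(fr)
            else:
                self.n_zero_length += 1
        if len(self._pending) >= self.batch_size:
            self.flush()

    def flush(self) -> None:
        if self._pending:
            write_finished_reads(self._pending, self.out_dir, self.fasta_name)
            self._pending = []

    def write_summary(self, path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
        """Sequencing summary built from the exact internal event log."""
        if path is None:
            path = self.out_dir / "sequencing_summary.txt"
        return summary_from_finished_reads(self.records, path)

    def close(self) -> None:
        if not self._closed:
            self.flush()
            self.fasta_path.touch(exist_ok=True)
            self._closed = True


def summary_from_finished_reads(
    finished: Sequence[FinishedRead],
    out_tsv: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Sequencing summary straight from the event log (includes zero-length
    reads); rows sorted by (channel, start_time)."""
    rows = [
        {
            "read_id": record_id_for(fr),
            "channel": fr.channel,
            "start_time": fr.t_start,
            "duration": fr.duration,
            "sequence_length_template": len(fr.sequence),
            "end_reason": END_REASON_TOKENS[fr.end_reason],
            "passes_filtering": True,
        }
        for fr in finished
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if len(df):
        df = df.sort_values(["channel", "start_time"], kind="mergesort").reset_index(
            drop=True
        )
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df


def build_sequencing_summary(
    fasta_paths: Union[str, Path, Iterable[Union[str, Path]]],
    out_tsv: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Rebuild a sequencing summary from simulator FASTA headers alone.

    No basecalling and no sequence inspection: one row per record, read
    directly from the metadata header, in O(records).
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    rows = []
    for path in fasta_paths:
        with open(path) as fh:
            for record in SeqIO.parse(fh, "fasta"):
                row = parse_fasta_header(record.description)
                rows.append(
                    {
                        "read_id": row["read_id"],
                        "channel": row["channel"],
                        "start_time": row["start_time"],
                        "duration": row["duration"],
                        "sequence_length_template": row["seq_len"],
                        "end_reason": row["end_reason"],
                        "passes_filtering": True,
                    }
                )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if len(df):
        df = df.sort_values(["channel", "start_time"], kind="mergesort").reset_index(
            drop=True
        )
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df


class StatsReporter:
    """Collects per-channel statistics snapshots at regular intervals.

    Each report appends one row per channel to an in-memory table (written
    as TSV on :meth:`write`) and logs one aggregate line.
    """

    def __init__(self, interval: float = 10.0):
        if interval <= 0:
            raise ValueError("interval must be > 0")
        self.interval = interval
        self.rows: List[dict] = []
        self.n_reports = 0

    def report(self, stats: Sequence[ChannelStats], t_now: float) -> None:
        self.n_reports += 1
        for s in stats:
            self.rows.append(
                {
                    "t": t_now,
                    "channel": s.channel,
                    "n_reads_finished": s.n_reads_finished,
                    "n_basepairs": s.n_basepairs,
                    "n_rejections": s.n_rejections,
                    "n_missed_rejections": s.n_missed_rejections,
                    "n_stop_receiving": s.n_stop_receiving,
                    "channel_alive": s.channel_alive,
                }
            )
        logger.info(
            "t=%.1f s: %d reads, %d bp, %d rejections (%d missed), %d/%d channels alive",
            t_now,
            sum(s.n_reads_finished for s in stats),
            sum(s.n_basepairs for s in stats),
            sum(s.n_rejections for s in stats),
            sum(s.n_missed_rejections for s in stats),
            sum(s.channel_alive for s in stats),
            len(stats),
        )

    def write(self, path: Union[str, Path]) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.to_csv(path, sep="\t", index=False)
        return df


# ---- raw-signal prototype ---------------------------------------------------


@dataclass
class PoreModel:
    """K-mer current-level table for synthesizing raw signal."""

    k: int
    level_mean: Dict[str, float]  # k-mer -> mean current (pA)
    samples_per_base: int = 10
    noise_sd: float = 1.5

    def __post_init__(self):
        if self.samples_per_base < 1:
            raise ValueError("samples_per_base must be >= 1")
        if len(self.level_mean) != 4**self.k:
            raise ValueError(
                f"pore model must cover all {4 ** self.k} {self.k}-mers "
                f"(got {len(self.level_mean)})"
            )


def default_pore_model(
    k: int = 6, samples_per_base: int = 10, noise_sd: float = 1.5
) -> PoreModel:
    """A small synthetic pore model: deterministic pseudo-random levels in a
    plausible nanopore current range (~60-130 pA), covering all 4^k k-mers.
    Stands in for ONT's published k-mer model tables in tests and demos."""
    rng = np.random.default_rng(6364136)
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    levels = rng.uniform(60.0, 130.0, size=len(kmers))
    return PoreModel(
        k=k,
        level_mean=dict(zip(kmers, levels.tolist())),
        samples_per_base=samples_per_base,
        noise_sd=noise_sd,
    )


def load_pore_model(
    path: Union[str, Path], samples_per_base: int = 10, noise_sd: float = 1.5
) -> PoreModel:
    """Load an ONT-style k-mer model TSV (columns ``kmer``, ``level_mean``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("kmer", "level_mean"):
        if col not in df.columns:
            raise ValueError(f"pore model file missing column {col!r}")
    level_mean = dict(zip(df["kmer"].astype(str), df["level_mean"].astype(float)))
    k = len(next(iter(level_mean)))
    return PoreModel(
        k=k,
        level_mean=level_mean,
        samples_per_base=samples_per_base,
        noise_sd=noise_sd,
    )


def sequence_to_raw_signal(
    sequence: str, model: PoreModel, seed: Optional[int] = None
) -> np.ndarray:
    """Convert a basecalled sequence to a synthetic raw current trace.

    Each k-mer window (stride 1) contributes ``samples_per_base`` samples
    at its table level plus Gaussian noise; output length is
    ``(len(sequence) - k + 1) * samples_per_base``.  Windows containing
    ``N`` map to the mean of all table levels.
    """
    seq = sequence.upper()
    if len(seq) < model.k:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than k={model.k}"
        )
    fallback = float(np.mean(list(model.level_mean.values())))
    n_windows = len(seq) - model.k + 1
    levels = np.empty(n_windows, dtype=float)
    for i in range(n_windows):
        kmer = seq[i : i + model.k]
        levels[i] = model.level_mean.get(kmer, fallback)
    signal = np.repeat(levels, model.samples_per_base)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, model.noise_sd, size=signal.shape)
    return signal
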