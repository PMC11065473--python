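"""Full-read input handling.

Loads pools of full-length reads from FASTA, shuffles them reproducibly,
and dispenses them to channels on demand.  Also understands NanoSim-style
read ids (``<ref>_<pos>_<aligned|unaligned>_<idx>_<F|R>_<head>_<middle>_<tail>``)
so that truncated reads can have their reference-length field rewritten.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "FullRead",
    "NanoSimMeta",
    "ReadPool",
    "load_reads",
    "parse_nanosim_id",
    "format_nanosim_id",
    "rewrite_nanosim_id",
]

_VALID_SEQ_RE = re.compile(r"^[ACGTN]+$")

_NANOSIM_ID_RE = re.compile(
    r"^(?P<ref>.+)_(?P<pos>\d+)_(?P<aligned>aligned|unaligned)_(?P<idx>\d+)"
    r"_(?P<strand>[FR])_(?P<head>\d+)_(?P<middle>\d+)_(?P<tail>\d+)$"
)


@dataclass(frozen=True)
class NanoSimMeta:
    """Parsed fields of a NanoSim read id.

    ``head_len``/``tail_len`` are the unaligned flanks of the read and
    ``middle_ref_len`` is the length of the aligned reference segment.
    """

    reference_name: str
    reference_start: int
    aligned_flag: str  # "aligned" | "unaligned"
    read_index: int
    strand: str  # "F" | "R"
    head_len: int
    middle_ref_len: int
    tail_len: int


@dataclass(frozen=True)
class FullRead:
    """One input read: a unique id plus an uppercase ACGTN sequence."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def nanosim(self) -> Optional[NanoSimMeta]:
        return parse_nanosim_id(self.read_id)


class ReadPool:
    """A seeded-shuffled pool of reads, each dispensed at most once.

    Dispensing is lazy: channels pull reads only when they need them, so a
    channel that dies early never consumes pool reads.
    """

    def __init__(self, reads: Sequence[FullRead], seed: Optional[int] = None):
        self._reads = list(reads)
        if seed is not None:
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(self._reads))
            self._reads = [self._reads[i] for i in order]
        self._cursor = 0

    def __len__(self) -> int:
        return len(self._reads)

    @property
    def n_remaining(self) -> int:
        return len(self._reads) - self._cursor

    @property
    def exhausted(self) -> bool:
        return self._cursor >= len(self._reads)

    def next_read(self) -> Optional[FullRead]:
        """Return the next undispensed read, or ``None`` once exhausted.

        Exhaustion is idempotent: repeated calls keep returning ``None``.
        """
        if self.exhausted:
            return None
        read = self._reads[self._cursor]
        self._cursor += 1
        return read


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_reads(
    fasta_paths: Union[str, Path, Iterable[Union[str, Path]]],
    seed: Optional[int] = None,
) -> ReadPool:
    """Load FASTA file(s) into a seeded-shuffled :class:`ReadPool`.

    The record id is the first whitespace-delimited token of the header and
    must be unique across all files.  Sequences are uppercased; ``N`` bases
    pass through, any symbol outside ``ACGTN`` is an error.  The shuffle is
    global across files with a single RNG seeded by ``seed``.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    reads: list[FullRead] = []
    seen: set[str] = set()
    for path in fasta_paths:
        n_before = len(reads)
        with _open_text(path) as fh:
            for record in SeqIO.parse(fh, "fasta"):
                seq = str(record.seq).upper()
                if not seq:
                    raise ValueError(f"empty sequence for read {record.id!r} in {path}")
                if not _VALID_SEQ_RE.match(seq):
                    bad = sorted(set(seq) - set("ACGTN"))
                    raise ValueError(
                        f"read {record.id!r} contains invalid characters {bad}"
                    )
                if record.id in seen:
                    raise ValueError(f"duplicate read id {record.id!r}")
                seen.add(record.id)
                reads.append(FullRead(read_id=record.id, sequence=seq))
        if len(reads) == n_before:
            raise ValueError(f"FASTA file {path} contains no records")
    return ReadPool(reads, seed=seed)


def parse_nanosim_id(read_id: str) -> Optional[NanoSimMeta]:
    """Parse a NanoSim-style read id, or return ``None`` if it does not match.

    Reference names may themselves contain underscores; the six trailing
    numeric/flag fields are matched greedily from the right.
    """
    m = _NANOSIM_ID_RE.match(read_id)
    if m is None:
        return None
    return NanoSimMeta(
        reference_name=m.group("ref"),
        reference_start=int(m.group("pos")),
        aligned_flag=m.group("aligned"),
        read_index=int(m.group("idx")),
        strand=m.group("strand"),
        head_len=int(m.group("head")),
        middle_ref_len=int(m.group("middle")),
        tail_len=int(m.group("tail")),
    )


def format_nanosim_id(meta: NanoSimMeta) -> str:
    """Inverse of :func:`parse_nanosim_id` (round-trips exactly)."""
    return (
        f"{meta.reference_name}_{meta.reference_start}_{meta.aligned_flag}"
        f"_{meta.read_index}_{meta.strand}_{meta.head_len}_{meta.middle_ref_len}"
        f"_{meta.tail_len}"
    )


def rewrite_nanosim_id(
    meta: NanoSimMeta, effective_read_len: int, full_read_len: int
) -> str:
    """Rewrite a NanoSim id so its fields reflect a truncated read.

    Truncation accounting: the head portion of the read is consumed first,
    then the middle, then the tail.  The reference-length (middle) field is
    rescaled proportionally to the consumed fraction of the read's middle
    part; the tail field is whatever of the truncated read remains beyond
    head + consumed middle.  ``effective == full`` leaves the id unchanged.
    """
    if not 0 <= effective_read_len <= full_read_len:
        raise ValueError(
            f"effective_read_len {effective_read_len} outside [0, {full_read_len}]"
        )
    if effective_read_len == full_read_len:
        return format_nanosim_id(meta)
    middle_read_part = full_read_len - meta.head_len - meta.tail_len
    consumed_middle = min(
        max(effective_read_len - meta.head_len, 0), max(middle_read_part, 0)
    )
    frac = consumed_middle / max(middle_read_part, 1)
    new_middle_ref = int(round(meta.middle_ref_len * min(max(frac, 0.0), 1.0)))
    new_tail = max(0, effective_read_len - meta.head_len - consumed_middle)
    new_meta = replace(meta, middle_ref_len=new_middle_ref, tail_len=new_tail)
    return format_nanosim_id(new_meta)
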