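"""Synthetic inputs with known ground truth.

Everything the simulator consumes can be generated here without
downloads: random read sets (plain or NanoSim-id-styled) and synthetic
sequencing summaries whose per-channel gap structure is returned exactly
as generated, so fitting code can be checked against truth.

The generated summaries emulate the structure of a real flowcell run —
a first-read delay, alternating reads and gaps, occasional long
blockages, and permanent channel death — with lognormal read lengths and
exponential gap durations.  They do not model basecalling errors, quality
scores, pore-specific speed variation, or mux-scan interruptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .gap_samplers import ChannelGapSeries, Gap
from .read_source import FullRead

__all__ = [
    "SyntheticRunSpec",
    "generate_reads",
    "write_reads_fasta",
    "generate_summary",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticRunSpec:
    """Parameters of a synthetic flowcell run.

    Defaults describe a plausible small MinION-like run: 5 kb median
    reads at 450 bp/s, ~1 s pore-loading gaps, occasional ~60 s
    blockages, channels dying between one and two hours in.
    """

    n_channels: int = 32
    n_reads_per_channel: int = 40
    read_length_log_mu: float = math.log(5000.0)  # log-bp
    read_length_log_sigma: float = 0.5
    short_gap_mean: float = 1.0  # seconds, exponential
    long_gap_mean: float = 60.0  # seconds, exponential
    long_gap_prob: float = 0.05  # per inter-read gap
    death_time_min: float = 3600.0  # seconds, uniform
    death_time_max: float = 7200.0
    bp_per_second: float = 450.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1 or self.n_reads_per_channel < 1:
            raise ValueError("channel and read counts must be >= 1")
        for name in ("short_gap_mean", "long_gap_mean", "bp_per_second"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.long_gap_prob <= 1.0:
            raise ValueError("long_gap_prob must be in [0, 1]")
        if not 0 < self.death_time_min <= self.death_time_max:
            raise ValueError("need 0 < death_time_min <= death_time_max")


def generate_reads(
    n: int,
    mean_length: float = 5000.0,
    length_log_sigma: float = 0.5,
    nanosim_style: bool = False,
    seed: int = 0,
    min_length: int = 50,
) -> List[FullRead]:
    """Generate ``n`` uniform-random ACGT reads with lognormal lengths.

    With ``nanosim_style`` the ids follow the NanoSim grammar with
    self-consistent head/middle/tail fields summing to the read length.
    Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu = math.log(mean_length)
    lengths = np.maximum(
        rng.lognormal(mean=mu, sigma=length_log_sigma, size=n).astype(int), min_length
    )
    reads = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(_BASES, size=int(length)))
        if nanosim_style:
            head = int(rng.integers(0, max(length // 20, 1)))
            tail = int(rng.integers(0, max(length // 20, 1)))
            middle = int(length) - head - tail
            ref = f"chr{1 + int(rng.integers(22))}"
            pos = int(rng.integers(0, 10_000_000))
            strand = "F" if rng.random() < 0.5 else "R"
            read_id = f"{ref}_{pos}_aligned_{i}_{strand}_{head}_{middle}_{tail}"
        else:
            read_id = f"synthetic_read_{i:06d}"
        reads.append(FullRead(read_id=read_id, sequence=seq))
    return reads


def write_reads_fasta(reads: List[FullRead], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    return path


def generate_summary(
    spec: SyntheticRunSpec,
    out_tsv: Optional[Union[str, Path]] = None,
) -> Tuple[pd.DataFrame, Dict[int, ChannelGapSeries]]:
    """Synthesize a sequencing-summary table plus its exact gap series.

    Per channel: a first-read delay, then alternating reads (duration =
    length / bp_per_second) and sampled gaps, stopping at the channel's
    death time or read budget.  No read starts after the death time.  The
    returned series are exactly what
    :func:`~poreplay.gap_samplers.extract_gap_series` recovers from the
    table.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth: Dict[int, ChannelGapSeries] = {}
    for ch in range(1, spec.n_channels + 1):
        death = rng.uniform(spec.death_time_min, spec.death_time_max)
        first_delay = rng.exponential(spec.short_gap_mean)
        series = ChannelGapSeries(channel=ch, first_read_delay=first_delay)
        t = first_delay
        n_written = 0
        while n_written < spec.n_reads_per_channel and t <= death:
            length = max(
                int(
                    rng.lognormal(
                        mean=spec.read_length_log_mu, sigma=spec.read_length_log_sigma
                    )
                ),
                50,
            )
            duration = length / spec.bp_per_second
            rows.append(
                {
                    "read_id": f"ch{ch}_read{n_written}",
                    "channel": ch,
                    "start_time": t,
                    "duration": duration,
                    "sequence_length_template": length,
                    "end_reason": "signal_positive",
                    "passes_filtering": True,
                }
            )
            n_written += 1
            t_end = t + duration
            series.channel_end_time = t_end
            if n_written >= spec.n_reads_per_channel:
                break
            if rng.random() < spec.long_gap_prob:
                gap = rng.exponential(spec.long_gap_mean)
            else:
                gap = rng.exponential(spec.short_gap_mean)
            t_next = t_end + gap
            if t_next > death:
                break
            # store the float-rounded difference so that re-deriving the gap
            # from the written start times reproduces it bit-for-bit
            series.gaps.append(Gap(t_at=t_end, duration=t_next - t_end))
            t = t_next
        # float round-trip through the TSV text is exact (repr-based),
        # so the truth series matches extraction from the file exactly
        truth[ch] = series
    df = pd.DataFrame(rows)
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df, truth
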