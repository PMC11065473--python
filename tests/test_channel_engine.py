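"""Channel state-machine semantics: timing, chunks, actions, mux scans, stats."""

import numpy as np
import pytest

from conftest import build_engine
from poreplay.channel_engine import Inactive, ReadEndReason
from poreplay.read_source import FullRead


def fixed_reads(lengths, prefix="r"):
    rng = np.random.default_rng(0)
    return [
        FullRead(f"{prefix}{i}", "".join(rng.choice(list("ACGT"), size=L)))
        for i, L in enumerate(lengths)
    ]


class TestAdvanceTiming:
    def test_read_completion_closed_form(self):
        eng = build_engine(fixed_reads([450]), start_delay_seconds=1.0)
        finished = eng.advance(2.0)
        assert len(finished) == 1
        fr = finished[0]
        assert fr.end_reason == ReadEndReason.FINISHED
        assert fr.t_start == 0.0
        assert fr.duration == pytest.approx(2.0)
        assert len(fr.sequence) == 450

    def test_zero_advance_is_identity(self):
        eng = build_engine(fixed_reads([450]))
        eng.advance(0.5)
        el_before = eng.channels[0].element
        assert eng.advance(0.5) == []
        assert eng.channels[0].element is el_before

    def test_backwards_advance_is_error(self):
        eng = build_engine(fixed_reads([450]))
        eng.advance(1.0)
        with pytest.raises(ValueError):
            eng.advance(0.5)

    def test_pool_exhaustion_makes_channel_inactive(self):
        eng = build_engine(fixed_reads([45]), start_delay_seconds=0.0)
        eng.advance(10.0)
        assert isinstance(eng.channels[0].element, Inactive)
        assert not eng.channels[0].stats.channel_alive
        assert eng.advance(20.0) == []

    def test_back_to_back_reads_with_zero_gap(self):
        # peak throughput: active time fully covered by start delay + bp time
        eng = build_engine(
            fixed_reads([450, 450, 450]), short_gap=0.0, start_delay_seconds=0.5
        )
        finished = eng.advance(4.5)
        assert [f.end_reason for f in finished] == [ReadEndReason.FINISHED] * 3
        assert [f.t_start for f in finished] == [0.0, 1.5, 3.0]


class TestChunks:
    def test_chunk_availability_closed_form(self):
        eng = build_engine(
            fixed_reads([450]),
            start_delay_seconds=0.0,
            min_chunk_size=200,
        )
        eng.advance(0.6)
        chunk = eng.visible_chunk(1)
        assert chunk is not None
        assert chunk.offset == 0
        assert len(chunk.sequence) == 270
        # immediately again: no new basepairs
        assert eng.visible_chunk(1) is None

    def test_chunks_are_contiguous_prefix(self):
        eng = build_engine(
            fixed_reads([900]), start_delay_seconds=0.0, min_chunk_size=100
        )
        eng.advance(0.0)  # process the zero-length initial gap
        read = eng.channels[0].element.read
        got = ""
        for k in range(1, 8):
            eng.advance(k * 0.25)
            c = eng.visible_chunk(1)
            if c is not None:
                assert c.offset == len(got)
                got += c.sequence
        assert read.sequence.startswith(got)
        assert len(got) > 0

    def test_basecall_delay_slows_visibility_not_molecule(self):
        eng = build_engine(
            fixed_reads([450]),
            start_delay_seconds=0.0,
            basecall_delay_per_bp=1.0 / 450.0,  # halves visible rate
            min_chunk_size=1,
        )
        eng.advance(0.5)
        c = eng.visible_chunk(1)
        assert len(c.sequence) == 112  # floor(0.5 / (2/450))
        # physical position is unaffected: unblock truncates at 225 bp
        assert eng.unblock(1) == "succeeded"
        assert len(eng.finished_reads[-1].sequence) == 225

    def test_no_chunk_during_gap_or_after_stop(self):
        eng = build_engine(fixed_reads([450, 450]), short_gap=5.0)
        assert eng.visible_chunk(1) is None  # initial gap
        eng.advance(5.0)  # read starts
        eng.advance(6.5)
        eng.stop_receiving(1)
        assert eng.visible_chunk(1) is None


class TestUnblock:
    def test_unblock_truncates_at_physical_position(self):
        eng = build_engine(fixed_reads([900]), start_delay_seconds=1.0)
        eng.advance(2.0)  # 1 s of actual sequencing
        assert eng.unblock(1) == "succeeded"
        fr = eng.finished_reads[-1]
        assert fr.end_reason == ReadEndReason.UNBLOCKED
        assert len(fr.sequence) == 450
        assert fr.sequence == eng.pool._reads[0].sequence[:450]

    def test_unblock_inserts_unblock_delay(self):
        eng = build_engine(
            fixed_reads([900, 450]),
            short_gap=0.5,
            start_delay_seconds=0.0,
            unblock_delay=0.25,
        )
        eng.advance(1.0)
        eng.unblock(1)
        # next read starts after unblock delay + one sampled gap
        eng.advance(10.0)
        second = [f for f in eng.finished_reads if f.original_read_id == "r1"][0]
        assert second.t_start == pytest.approx(1.0 + 0.25 + 0.5)

    def test_unblock_finished_read_is_missed(self):
        eng = build_engine(fixed_reads([45, 900]), start_delay_seconds=0.0)
        eng.advance(0.5)  # first read done at 0.1, second in progress
        assert eng.unblock(1, read_id="r0") == "missed"
        assert eng.channels[0].stats.n_missed_rejections == 1

    def test_unblock_during_gap_is_missed(self):
        eng = build_engine(fixed_reads([450]), short_gap=10.0)
        eng.advance(1.0)
        assert eng.unblock(1) == "missed"

    def test_unblock_during_start_delay_emits_zero_length(self):
        eng = build_engine(fixed_reads([450]), start_delay_seconds=2.0)
        eng.advance(1.0)
        assert eng.unblock(1) == "succeeded"
        assert eng.finished_reads[-1].sequence == ""


class TestStopReceiving:
    def test_full_read_still_written(self):
        eng = build_engine(fixed_reads([450]), start_delay_seconds=0.0)
        eng.advance(0.5)
        assert eng.stop_receiving(1) == "succeeded"
        finished = eng.advance(2.0)
        assert finished[0].end_reason == ReadEndReason.FINISHED
        assert len(finished[0].sequence) == 450

    def test_idempotent_and_wrong_id_missed(self):
        eng = build_engine(fixed_reads([450]), start_delay_seconds=0.0)
        eng.advance(0.5)
        assert eng.stop_receiving(1, read_id="r0") == "succeeded"
        assert eng.stop_receiving(1, read_id="r0") == "succeeded"
        assert eng.channels[0].stats.n_stop_receiving == 1
        assert eng.stop_receiving(1, read_id="nope") == "missed"


class TestMuxScan:
    def test_scan_truncates_read_in_progress(self):
        eng = build_engine(fixed_reads([900]), start_delay_seconds=0.0)
        eng.advance(1.0)
        finished = eng.trigger_mux_scan(duration=5.0)
        assert len(finished) == 1
        assert finished[0].end_reason == ReadEndReason.MUX_SCAN_ENDED
        assert len(finished[0].sequence) == 450

    def test_long_gap_resumes_with_remaining_duration(self):
        # long gap of 100 s starting at t=2; scan of 10 s at t=32
        eng = build_engine(
            fixed_reads([450, 450]),
            long_gap=100.0,
            long_gap_every_n_reads=1,
            start_delay_seconds=1.0,
        )
        eng.advance(32.0)  # read [0,2), long gap [2,102), 30 s elapsed
        eng.trigger_mux_scan(duration=10.0)
        eng.advance(500.0)
        second = [f for f in eng.finished_reads if f.original_read_id == "r1"][0]
        # scan [32,42) then 70 s of remaining gap -> read starts at 112
        assert second.t_start == pytest.approx(112.0)

    def test_inactive_channel_unaffected(self):
        eng = build_engine(fixed_reads([45]), start_delay_seconds=0.0)
        eng.advance(10.0)
        assert isinstance(eng.channels[0].element, Inactive)
        eng.trigger_mux_scan(duration=5.0)
        assert isinstance(eng.channels[0].element, Inactive)

    def test_overlapping_scans_error(self):
        eng = build_engine(fixed_reads([450, 450]))
        eng.advance(1.0)
        eng.trigger_mux_scan(duration=10.0)
        with pytest.raises(ValueError, match="already active"):
            eng.trigger_mux_scan(duration=1.0)

    def test_automatic_scans_no_read_straddles_scan(self):
        reads = fixed_reads(list(np.random.default_rng(3).integers(50, 800, 60)))
        eng = build_engine(
            reads,
            n_channels=4,
            short_gap=0.2,
            start_delay_seconds=0.2,
            mux_scan_period=10.0,
            mux_scan_duration=2.0,
        )
        eng.advance(60.0)
        eng.finish_run()
        scans = [(k * 10.0, k * 10.0 + 2.0) for k in range(1, 6)]
        for fr in eng.finished_reads:
            t0, t1 = fr.t_start, fr.t_start + fr.duration
            for s0, s1 in scans:
                assert not (t0 < s0 and t1 > s0 + 1e-9), (fr, (s0, s1))


class TestStats:
    def test_fresh_stats_all_zero(self):
        eng = build_engine(fixed_reads([450]))
        for s in eng.collect_stats():
            assert s.n_reads_finished == s.n_basepairs == s.n_rejections == 0
            assert s.channel_alive

    def test_counts_after_one_read(self):
        eng = build_engine(fixed_reads([450]), start_delay_seconds=0.0)
        eng.advance(2.0)
        s = eng.collect_stats()[0]
        assert s.n_reads_finished == 1
        assert s.n_basepairs == 450

    def test_basepair_conservation_and_monotone_counters(self):
        rng = np.random.default_rng(9)
        reads = fixed_reads(list(rng.integers(50, 600, 80)))
        eng = build_engine(reads, n_channels=8, short_gap=0.3, start_delay_seconds=0.2)
        prev = {s.channel: s for s in eng.collect_stats()}
        for k in range(1, 40):
            eng.advance(k * 0.5)
            if k % 5 == 0:
                ch = int(rng.integers(1, 9))
                eng.unblock(ch)
            for s in eng.collect_stats():
                p = prev[s.channel]
                assert s.n_reads_finished >= p.n_reads_finished
                assert s.n_basepairs >= p.n_basepairs
                assert s.n_rejections >= p.n_rejections
                assert s.n_missed_rejections >= p.n_missed_rejections
                prev[s.channel] = s
        eng.finish_run()
        total_bp = sum(len(f.sequence) for f in eng.finished_reads)
        assert total_bp == sum(s.n_basepairs for s in eng.collect_stats())

    def test_collect_stats_returns_snapshots(self):
        eng = build_engine(fixed_reads([450]))
        snap = eng.collect_stats()[0]
        snap.n_basepairs = 10**9
        assert eng.collect_stats()[0].n_basepairs == 0


class TestPrefixProperty:
    def test_all_end_reasons_emit_prefixes(self):
        rng = np.random.default_rng(4)
        reads = fixed_reads(list(rng.integers(50, 900, 50)))
        by_id = {r.read_id: r for r in reads}
        eng = build_engine(
            reads,
            n_channels=4,
            short_gap=0.3,
            start_delay_seconds=0.3,
            mux_scan_period=12.0,
            mux_scan_duration=1.0,
        )
        for k in range(1, 60):
            eng.advance(k * 0.5)
            if k % 4 == 0:
                eng.unblock(int(rng.integers(1, 5)))
        eng.finish_run()
        reasons = {f.end_reason for f in eng.finished_reads}
        assert len(reasons) >= 3  # finished, unblocked, mux/run-ended
        for fr in eng.finished_reads:
            full = by_id[fr.original_read_id].sequence
            assert full.startswith(fr.sequence)
            if fr.end_reason == ReadEndReason.FINISHED:
                assert fr.sequence == full
            assert fr.duration + 1e-9 >= len(fr.sequence) / 450.0
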