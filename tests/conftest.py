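import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from poreplay.channel_engine import SequencerEngine, SimParams
from poreplay.gap_samplers import make_constant_gap_sampler
from poreplay.read_source import ReadPool
from poreplay.synthetic_fixtures import generate_reads


@pytest.fixture
def small_reads():
    """Twenty random reads, ~300 bp, deterministic."""
    return generate_reads(20, mean_length=300, seed=11)


def build_engine(
    reads,
    n_channels=1,
    short_gap=0.0,
    long_gap=None,
    long_gap_every_n_reads=None,
    shuffle_seed=None,
    **params,
):
    """Engine over a constant-gap sampler; short_gap=0 starts reads at t=0."""
    defaults = dict(
        n_channels=n_channels,
        bp_per_second=450.0,
        min_chunk_size=200,
        basecall_delay_per_bp=0.0,
        unblock_delay=0.1,
        start_delay_seconds=1.0,
    )
    defaults.update(params)
    pool = ReadPool(reads, seed=shuffle_seed)
    sampler = make_constant_gap_sampler(short_gap, long_gap, long_gap_every_n_reads)
    return SequencerEngine(SimParams(**defaults), pool, sampler)


@pytest.fixture
def engine_factory():
    return build_engine
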