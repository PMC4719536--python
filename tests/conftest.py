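import pytest

from bacpool import simulate as sim


@pytest.fixture(scope="session")
def small_pool():
    """Four non-repetitive 10 kb clones — fast to assemble and align."""
    return sim.simulate_pool(
        "poolA", n_clones=4, insert_length=10_000, repeat_fraction=0.0, seed=11
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Short-read config scaled for unit tests."""
    return sim.SimConfig(
        seed=23,
        read_length=70,
        pe_insert_mean=300.0,
        pe_insert_sd=30.0,
        ecoli_fraction=0.10,
        vector_fraction=0.04,
        clonal_fraction=0.006,
    )


@pytest.fixture(scope="session")
def small_pool_reads(small_pool, small_cfg):
    pairs, refs = sim.simulate_pool_reads(small_pool, target_coverage=25.0, cfg=small_cfg)
    return pairs, refs
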