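import numpy as np
import pytest

from svclique.model import SVCall, SVType


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_del(call_id, tool, chrom, left, right):
    return SVCall.deletion(call_id, tool, chrom, left, right)


def make_ins(call_id, tool, chrom, pos, length):
    return SVCall.insertion(call_id, tool, chrom, pos, length)


def random_call(rng, call_id, tool, chroms=("chr1", "chr2"), max_pos=100_000,
                min_len=20, max_len=400):
    """A random canonical call (used by round-trip and graph oracles)."""
    chrom = chroms[int(rng.integers(len(chroms)))]
    length = int(rng.integers(min_len, max_len + 1))
    if rng.random() < 0.5:
        left = int(rng.integers(2, max_pos))
        return make_del(call_id, tool, chrom, left, left + length - 1)
    pos = int(rng.integers(1, max_pos))
    if rng.random() < 0.1:
        length = None
    return make_ins(call_id, tool, chrom, pos, length)


@pytest.fixture(scope="session")
def standard_scenario():
    """The package's standard 2 Mb / ~600-event synthetic study, shared by
    the slower end-to-end tests."""
    from svclique.synth import benchmark_scenario

    chrom_lengths, truth, callsets, specs = benchmark_scenario(seed=20_260_926)
    return {
        "chrom_lengths": chrom_lengths,
        "truth": truth,
        "callsets": callsets,
        "specs": specs,
        "profiles": {s.tool_id: s.profile() for s in specs},
    }
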