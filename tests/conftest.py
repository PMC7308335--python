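import numpy as np
import pytest

from repscan.io_core import GermlineSegment, Region, load_germline_registry


@pytest.fixture(scope="session")
def registry():
    return load_germline_registry("builtin")


@pytest.fixture(scope="session")
def by_kind(registry):
    from repscan.io_core import registry_by_kind
    return registry_by_kind(registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_region(seq: str, start: int = 0, chrom: str = "chrT", **kw) -> Region:
    return Region(chrom, start, start + len(seq), seq, **kw)


@pytest.fixture(scope="session")
def worked_example_segments():
    """Tiny ad-hoc germline for the junction-decomposition worked example."""
    v = GermlineSegment("TRBVX", "V", "TGTGCCAGCAGT", anchor_offset=0)
    d1 = GermlineSegment("TRBD1", "D", "GGGACAGGGGGC")
    d2 = GermlineSegment("TRBD2", "D", "GGGACTGGGGGGGC")
    j = GermlineSegment("TRBJX", "J", "AACACCGGGCAGCTCTTC", anchor_offset=15)
    return v, d1, d2, j
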