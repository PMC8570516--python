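import numpy as np
import pytest

from barcodesv.hmm import HMMParams
from barcodesv.postprocess import build_null_model


@pytest.fixture(scope="session")
def max_null():
    """Operational (max-over-placements) null at production sample size."""
    return build_null_model(mode="max", n=500, seed=12345)


@pytest.fixture(scope="session")
def pair_null():
    """Plain per-pair correlation null."""
    return build_null_model(mode="pair", n=500, seed=777)


@pytest.fixture
def default_params():
    return HMMParams()


@pytest.fixture
def tiny_params():
    """Relaxed constraints so tiny instances are enumerable."""
    return HMMParams(l=2, l_G=1, sigma_e=0.5)


def segment_key(segments):
    """Canonical tuple form of a segment list for equality checks."""
    return [
        (s.query_start, s.query_end, s.ref_start, s.ref_end, s.orientation)
        for s in segments
    ]


@pytest.fixture
def seg_key():
    return segment_key
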