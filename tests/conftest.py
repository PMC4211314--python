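"""Shared fixtures: tiny hand-built networks and stream factories."""

import numpy as np
import pytest

from hypermem import EdgeConfig, Hypernetwork, StreamSpec, generate_stream


@pytest.fixture
def line_cfg():
    return EdgeConfig(mode="fixed", k=2, topology="line")


@pytest.fixture
def ring_cfg():
    return EdgeConfig(mode="fixed", k=2, topology="ring")


@pytest.fixture
def ab_line_net(line_cfg):
    """d=4 line network holding A=(1,2,3,4) and B=(5,2,3,6)."""
    net = Hypernetwork(4, "line", 10.0)
    net.encode((1, 2, 3, 4), line_cfg)
    net.encode((5, 2, 3, 6), line_cfg)
    return net


@pytest.fixture
def stream_factory():
    def make(n=300, seed=0, **kwargs):
        return generate_stream(StreamSpec(n=n, seed=seed, **kwargs)).instances

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
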