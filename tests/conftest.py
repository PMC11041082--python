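import numpy as np
import pytest

from platalloc import PlatformDesign

from _oracles import random_design_params


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_designs(rng):
    """A reproducible batch of valid three-period designs."""

    def make(n: int, min_frac: float = 0.02):
        out = []
        for _ in range(n):
            r, p = random_design_params(rng, min_frac=min_frac)
            out.append(PlatformDesign(N=1.0, r=r, p=p))
        return out

    return make


@pytest.fixture
def symmetric_design():
    """Three equal periods with the square-root-of-k period-2 allocation."""
    c = 1.0 / (1.0 + np.sqrt(2.0))
    t = (1.0 - c) / 2.0
    return PlatformDesign(
        N=92.0,
        r=(1 / 3, 1 / 3, 1 / 3),
        p=((0.5, 0.5, 0.0), (c, t, t), (0.5, 0.0, 0.5)),
    )
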