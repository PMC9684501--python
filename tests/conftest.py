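import numpy as np
import pytest

from hollingmap import ModelParams


@pytest.fixture
def example1_case1_I():
    return ModelParams(a=4.0, b=2.0, c=0.1, e=0.7, h=0.5926274349)


@pytest.fixture
def example1_case1_II():
    return ModelParams(a=3.0, b=2.5, c=0.2, e=0.5, h=1.022801547)


@pytest.fixture
def example2_case4_I():
    return ModelParams(a=1.5, b=0.5, c=0.1, e=2.0, h=3.7328)


@pytest.fixture
def example2_case6_flip():
    return ModelParams(a=1.5, b=0.5, c=0.09120395559, e=2.0, h=3.75)


@pytest.fixture
def example2_case6_ns():
    return ModelParams(a=1.5, b=0.5, c=0.09942, e=2.0, h=3.75)


@pytest.fixture
def example3_control():
    return ModelParams(a=9.0, b=2.0, c=0.25, e=0.5, h=0.5)


def random_valid_params(rng, n, require_b_gt_2c=False):
    """Seeded draws of valid parameter sets (b > c, optionally b > 2c)."""
    out = []
    while len(out) < n:
        a = rng.uniform(0.2, 5.0)
        b = rng.uniform(0.2, 3.0)
        factor = 2.0 if require_b_gt_2c else 1.0
        c = rng.uniform(0.02, b / factor * 0.9)
        e = rng.uniform(0.1, 3.0)
        h = rng.uniform(0.05, 2.0)
        out.append(ModelParams(a=a, b=b, c=c, e=e, h=h))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
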