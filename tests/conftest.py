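import numpy as np
import pytest

from stepstress import (
    CensoringScheme,
    GammaPrior,
    RateParams,
    load_illustrative_dataset,
    sufficient_stats,
)

# Monte-Carlo comparison design: true rates and the three n=40/60/80 schemes
TRUE_PARAMS = RateParams(2.0, 1.0, 4.0, 2.0)

SCHEME_40 = CensoringScheme(40, 15, 15, (0,) * 11 + (1, 1, 2, 1) + (0,) * 11 + (1, 1, 2, 1))
SCHEME_60 = CensoringScheme(60, 23, 23, ((0,) * 19 + (1, 2, 2, 2)) * 2)
SCHEME_80 = CensoringScheme(
    80, 30, 30, ((1, 1, 2, 1) + (0,) * 22 + (1, 2, 1, 1)) * 2
)


@pytest.fixture(scope="session")
def illustrative():
    return load_illustrative_dataset()


@pytest.fixture(scope="session")
def illustrative_stats(illustrative):
    return sufficient_stats(illustrative)


@pytest.fixture(scope="session")
def diffuse_prior():
    return GammaPrior.constant(0.5, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
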