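import numpy as np
import pytest

from adaptscan.simcortex.designs import (
    AdaptationTiming,
    LocalizerTiming,
    build_adaptation_design,
    build_localizer_design,
)


@pytest.fixture(scope="session")
def localizer_design():
    return build_localizer_design(run_index=0)


@pytest.fixture(scope="session")
def adaptation_design():
    return build_adaptation_design(run_index=0, seed=3)


@pytest.fixture(scope="session")
def localizer_timing():
    return LocalizerTiming()


@pytest.fixture(scope="session")
def adaptation_timing():
    return AdaptationTiming()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
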