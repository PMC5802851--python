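import numpy as np
import pytest

from hybridbnm import (AlphaDriveSpec, DriveTimeSeries, ModelParameters,
                       StructuralConnectome, make_am_alpha,
                       make_synthetic_connectome)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def single_node() -> StructuralConnectome:
    return StructuralConnectome(np.zeros((1, 1)))


@pytest.fixture(scope="session")
def connectome8() -> StructuralConnectome:
    return make_synthetic_connectome(8, seed=1)


@pytest.fixture()
def zero_drive():
    def make(n_regions: int = 1, duration: float = 1.0,
             rate: float = 1000.0) -> DriveTimeSeries:
        return DriveTimeSeries(
            np.zeros((n_regions, int(round(duration * rate)))), rate)

    return make


@pytest.fixture(scope="session")
def am_drive8() -> DriveTimeSeries:
    spec = AlphaDriveSpec(duration=120.0, n_regions=8,
                          envelope_kind="slow_am", seed=1)
    return make_am_alpha(spec)
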