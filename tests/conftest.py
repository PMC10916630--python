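import numpy as np
import pytest

from shelfkin import StorageSeries


@pytest.fixture
def exp_series():
    """Factory for noiseless exponential series C(t) = C0·exp(s·k·t)."""

    def make(k=0.0367, C0=0.82, times=None, direction=1,
             index_name="CSR", temperature=298.15):
        t = np.arange(0.0, 44.0, 4.0) if times is None else np.asarray(times, float)
        return StorageSeries(
            index_name=index_name,
            temperature=temperature,
            times=t,
            values=C0 * np.exp(direction * k * t),
        )

    return make


@pytest.fixture
def linear_series():
    """Factory for noiseless linear series C(t) = C0 + s·k·t."""

    def make(k=0.5, C0=10.0, times=None, direction=-1,
             index_name="viscosity", temperature=298.15):
        t = np.arange(0.0, 11.0) if times is None else np.asarray(times, float)
        return StorageSeries(
            index_name=index_name,
            temperature=temperature,
            times=t,
            values=C0 + direction * k * t,
        )

    return make
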