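import numpy as np
import pytest

from fiberhdim.types import FluorSpecies, InstrumentConfig


@pytest.fixture
def config() -> InstrumentConfig:
    return InstrumentConfig()


def mono(tau: float, peak: float = 630.0, width: float = 0.0, **kw) -> FluorSpecies:
    """Convenience mono-exponential species."""
    return FluorSpecies(
        name=f"mono_{tau}", lifetimes=(tau,), amplitudes=(1.0,),
        emission_peak=peak, emission_width=width, **kw,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
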