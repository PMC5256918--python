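import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def instrument_grid() -> np.ndarray:
    """The acquisition grid: 3600 -> 800 cm^-1 at 4 cm^-1 resolution."""
    return 3600.0 - 4.0 * np.arange(701)


@pytest.fixture(scope="session")
def ch3_grid(instrument_grid) -> np.ndarray:
    """Grid points of the 2992-2850 cm^-1 deconvolution window."""
    w = instrument_grid
    return w[(w >= 2850.0) & (w <= 2992.0)]


@pytest.fixture(scope="session")
def band_library():
    from methylscope.synthetic import default_dna_band_library

    return tuple(default_dna_band_library())
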