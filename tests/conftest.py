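import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plvnet.core import Parcellation, Recording

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NETWORKS = ("SMN", "DAN", "SN", "DMN", "CEN")


@pytest.fixture(scope="session")
def toy_parcellation() -> Parcellation:
    """10 regions, 2 per network — small enough for exact hand checks."""
    regions = [f"r{i}" for i in range(10)]
    return Parcellation(
        regions=regions,
        network_of={r: NETWORKS[i // 2] for i, r in enumerate(regions)},
    )


@pytest.fixture(scope="session")
def parcellation20() -> Parcellation:
    """20 regions, 4 per network — used for recovery simulations."""
    regions = [f"r{i}" for i in range(20)]
    return Parcellation(
        regions=regions,
        network_of={r: NETWORKS[i // 4] for i, r in enumerate(regions)},
    )


@pytest.fixture
def tone_recording() -> Recording:
    """3 channels of a pure 10 Hz tone, 8 s at 256 Hz."""
    fs = 256.0
    t = np.arange(int(8 * fs)) / fs
    x = 20.0 * np.cos(2 * np.pi * 10.0 * t)
    return Recording(data=np.vstack([x, x, x]), fs=fs,
                     labels=["C1", "C2", "C3"])
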