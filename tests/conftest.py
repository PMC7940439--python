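import numpy as np
import pytest

import calsensor as cs


@pytest.fixture(scope="session")
def ref_config() -> cs.ModelConfig:
    """Reference parameterization: R=300 nm, rho=5 nm, CD=15 nm, no buffer."""
    return cs.default_config()


@pytest.fixture(scope="session")
def time_grid() -> np.ndarray:
    """The default 7-decade log grid, thinned for test speed."""
    return np.logspace(-4, 3, 140)


@pytest.fixture(scope="session")
def ref_curve(ref_config, time_grid) -> cs.OccupancyCurve:
    """Single-ion occupancy on the reference configuration (residue series)."""
    return cs.occupancy_single(ref_config, time_grid, backend="series")


@pytest.fixture(scope="session")
def atp_config(ref_config) -> cs.ModelConfig:
    return cs.default_config(["ATP"])


@pytest.fixture(scope="session")
def efb_config(ref_config) -> cs.ModelConfig:
    return cs.default_config(["EFB"])


@pytest.fixture(scope="session")
def atp_series(atp_config):
    """Mobile-buffer residue series (pole search is the expensive part)."""
    return cs.residue_series(atp_config, t_min=1e-4)


@pytest.fixture(scope="session")
def efb_series(efb_config):
    """Fixed-buffer residue series."""
    return cs.residue_series(efb_config, t_min=1e-4)
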