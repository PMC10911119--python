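import numpy as np
import pytest

import fcsgrad as fg


@pytest.fixture(scope="session")
def vol() -> fg.FocalVolume:
    return fg.FocalVolume(w_xy=0.2, k=5.0)


@pytest.fixture(scope="session")
def lags() -> np.ndarray:
    return fg.default_lags(200, 1e-6, 1.0)


@pytest.fixture(scope="session")
def anterior_curve(vol, lags) -> fg.ACFCurve:
    """Noiseless two-component triplet curve, anterior-cytoplasm preset."""
    return fg.generate_acf("bcd/cytoplasm/anterior", vol, lags)


@pytest.fixture(scope="session")
def posterior_curve(vol, lags) -> fg.ACFCurve:
    return fg.generate_acf("bcd/cytoplasm/posterior", vol, lags)


@pytest.fixture(scope="session")
def coarse_grid() -> np.ndarray:
    return fg.default_grid(500.0, 2.0)


@pytest.fixture(scope="session")
def bcd_two_comp_steady(coarse_grid):
    """Relaxed steady state of the default Bcd-like two-component model."""
    p = fg.bcd_two_component_params()
    return p, fg.two_component_steady_state(p, x_grid=coarse_grid)
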