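import numpy as np
import pytest

from restplay.synthetic import SimConfig, simulate_full_experiment


@pytest.fixture(scope="session")
def default_session():
    """One full synthetic session at study-condition defaults."""
    bundle, truth = simulate_full_experiment(SimConfig(seed=11))
    return bundle, truth


@pytest.fixture(scope="session")
def coupled_session():
    """Session in which every reactivation is SWR-locked (planted lags
    50 / 180 ms), used for timing-recovery checks."""
    bundle, truth = simulate_full_experiment(
        SimConfig(seed=12, p_swr_coupled=1.0))
    return bundle, truth


@pytest.fixture(scope="session")
def default_spatial(default_session):
    """Spatial-cell classification of the default session (shared:
    the shuffle test is the expensive step)."""
    from restplay.spatial import SpatialCellDetector
    bundle, _ = default_session
    det = SpatialCellDetector(n_shuffles=200, seed=0)
    det.fit(bundle.run, position_cm=bundle.position_cm)
    return det


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
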