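import numpy as np
import pytest

from ctptrunc.deconv import ConcentrationCurve
from ctptrunc.synthetic import SimConfig, gamma_variate, simulate_ctp_scan


def small_config(**overrides) -> SimConfig:
    """Desk-scale simulator settings for fast unit tests."""
    defaults = dict(n_scans=4, tissue_grid=(24, 24, 2), voxel_volume_ml=0.5,
                    lesion_fraction=0.08, seed=7)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def sim_config():
    return small_config()


@pytest.fixture
def small_scan(sim_config):
    rng = np.random.default_rng(42)
    return simulate_ctp_scan(sim_config, rng, scan_id="fix001")


@pytest.fixture
def aif_conc():
    """Noise-free arterial concentration curve on a 90-sample 1 Hz grid."""
    t = (np.arange(90) + 1) * 1.0
    return ConcentrationCurve(gamma_variate(t, 10.0, 3.0, 1.5, 200.0), dt=1.0,
                              baseline_hu=0.0)
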