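import numpy as np
import pytest

from hisatkin.kinetics import TernaryModel
from hisatkin.synth import SimScenario, simulate_rate_grid

# Published wild-type constants used as simulation ground truth throughout:
# kcat 36.5 1/s, Km_AcCoA 19.8 uM, Km_His 215 uM at 20 nM enzyme; Ki_His is
# unreported and fixed at 200 uM (recovery must not depend on it).
ENZYME_UM = 0.02
TRUTH = {"kcat": 36.5, "km_accoa": 19.8, "km_his": 215.0}
KI_HIS = 200.0


@pytest.fixture(scope="session")
def wt_model():
    return TernaryModel.from_kcat(TRUTH["kcat"], ENZYME_UM, TRUTH["km_accoa"],
                                  TRUTH["km_his"], KI_HIS)


@pytest.fixture(scope="session")
def noise_free_grid(wt_model):
    """Noise-free initial-rate grid over the study's concentration grids."""
    sc = SimScenario(model=wt_model, seed=0)
    grid = simulate_rate_grid(sc)
    return grid[grid.his_uM > 0].reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
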