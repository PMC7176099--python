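import numpy as np
import pytest

from repforecast import SimConfig, StudyPair, simulate_pairs

DATA_DIR = __import__("pathlib").Path(__file__).parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def five_pairs():
    return [
        StudyPair("p01", 0.45, 32, 0.21, 65, 0.6),
        StudyPair("p02", 0.62, 28, 0.50, 30, 0.8),
        StudyPair("p03", 0.21, 120, 0.05, 240, 0.35),
        StudyPair("p04", -0.35, 45, -0.11, 90, 0.55),
        StudyPair("p05", 0.18, 60, 0.24, 60, 0.7),
    ]


@pytest.fixture
def simulated_project():
    return simulate_pairs(SimConfig(n_pairs=60, seed=11))


@pytest.fixture
def fixture_csv():
    return DATA_DIR / "pairs_small.csv"
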