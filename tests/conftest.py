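import numpy as np
import pytest

from barnet.library_tools import BarcodeLibrary
from barnet.synthetic_data import SimulationConfig, sample_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_library():
    return BarcodeLibrary.from_counts(
        {"ACGTACGTACGTACGTACGT": 2, "TGCATGCATGCATGCATGCA": 1, "GGCCAATTGGCCAATTGGCC": 1},
        library_id="tiny",
    )


@pytest.fixture
def skewed_library():
    return sample_library(500, 2.0, seed=7, library_id="skewed")


@pytest.fixture
def base_config():
    return SimulationConfig(
        seed=11,
        n_library_barcodes=500,
        library_skew_sigma=1.5,
        n_tva_cells=200,
        n_infections=60,
        p_source_death=0.5,
        p_direct_infection=0.05,
        p_intersource_connection=0.15,
        presyn_dispersion=2.0,
        g_count_leak_mean=0.0,
    )
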