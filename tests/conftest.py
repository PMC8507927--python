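import numpy as np
import pytest

from dropscreen import generate_library, plant_effects, simulate_baseline


@pytest.fixture
def tiny_design():
    """2 reliable genes x 5 shRNAs, 8-nt barcodes."""
    return generate_library(2, 10, barcode_length=8, seed=7)


@pytest.fixture
def small_design():
    """10 reliable genes, 52 shRNAs (2 genes get a 6th hairpin), 2 AUX hairpins."""
    return generate_library(10, 54, barcode_length=10, seed=1, n_reliable_shrnas=52)


@pytest.fixture
def small_effects(small_design):
    return plant_effects(small_design, fraction_essential=0.2,
                         fraction_condition_specific=0.5,
                         s_distribution=(0.5, 0.15), effective_fraction=0.8,
                         condition_specific_label="setting3",
                         background_sd=0.0, seed=3)


@pytest.fixture
def small_baseline(small_design):
    return simulate_baseline(small_design, dispersion=0.3, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
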